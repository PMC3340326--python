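"""Statistically controlled synthetic input bundles.

Emulates the structure of a strain-comparison liver microarray experiment
with QTL annotations, at gene level:

* genes of fixed 10 kb length placed uniformly on equal-length chromosomes;
* QTL intervals drawn as disjoint uniform segments covering a target
  fraction of the genome;
* baseline log2 expression: per-gene baseline level plus iid normal
  residual noise (no gene-gene correlation by default, so the
  normal-theory set test is calibrated; an equicorrelation knob adds a
  shared per-sample factor to emulate the correlation that inflates false
  positives on real arrays);
* disjoint pathways sampled from the gene pool; a spiked pathway has a
  controlled fraction of its members placed inside QTL regions and a mean
  log2 shift applied to exactly those in-QTL members in the
  high-phenotype group(s) — upward (U), downward (D), or with a random
  sign per gene (B).

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from the config, so a fixed seed gives a byte-reproducible bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from . import io_formats
from .gsa_core import Comparison
from .io_formats import ExpressionMatrix, GeneAnnotation, GeneSet, QTLRecord

GENE_LENGTH_BP = 10_000


@dataclass(frozen=True)
class SpikeSpec:
    """A pathway to spike with differential expression.

    fraction_in_qtl of the pathway's members are placed inside QTL regions
    and receive the effect (mean log2 shift) in the high-phenotype groups;
    mode B draws a random sign per gene.
    """

    set_name: str
    mode: str = "U"  # U | D | B
    effect_size: float = 1.0
    fraction_in_qtl: float = 0.5

    def __post_init__(self):
        if self.mode not in ("U", "D", "B"):
            raise ValueError(f"unknown spike mode {self.mode!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.fraction_in_qtl <= 1.0:
            raise ValueError("fraction_in_qtl must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated experiment.

    Defaults describe the global-null calibration experiment: 10,000 genes,
    100 disjoint pathways of 20 genes, QTL regions covering 30% of the
    genome, two strains with triplicate arrays and unit residual SD.
    """

    n_genes: int = 10_000
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (20, 20)
    n_samples_per_group: int = 3
    groups: tuple[str, ...] = ("high", "low")
    high_groups: tuple[str, ...] = ("high",)
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    equicorrelation: float = 0.0  # SD of a shared per-sample factor
    spiked_pathways: tuple[SpikeSpec, ...] = ()
    qtl_coverage: float = 0.3
    qtl_per_chromosome: int = 2
    chromosome_count: int = 19
    chromosome_length_bp: int = 100_000_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.qtl_coverage <= 1.0:
            raise ValueError("qtl_coverage must be in [0, 1]")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid pathway_size_range {self.pathway_size_range}")
        if hi > self.n_genes:
            raise ValueError("pathway larger than gene count")
        if self.n_pathways * hi > self.n_genes:
            raise ValueError(
                "disjoint pathways need n_pathways * max size <= n_genes "
                f"({self.n_pathways} * {hi} > {self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        unknown_high = set(self.high_groups) - set(self.groups)
        if unknown_high:
            raise ValueError(f"high_groups not in groups: {sorted(unknown_high)}")
        if not set(self.groups) - set(self.high_groups):
            raise ValueError("at least one low-phenotype group required")
        names = self.pathway_names()
        for spike in self.spiked_pathways:
            if spike.set_name not in names:
                raise ValueError(f"spiked pathway {spike.set_name!r} not among {len(names)} pathways")

    def pathway_names(self) -> list[str]:
        width = max(3, len(str(self.n_pathways)))
        return [f"pw{i:0{width}d}" for i in range(1, self.n_pathways + 1)]

    def comparisons(self) -> list[Comparison]:
        """All high-vs-low group pairs, in group order."""
        low = [g for g in self.groups if g not in self.high_groups]
        return [
            Comparison(f"{h}_vs_{l}", h, l)
            for h in self.high_groups
            for l in low
        ]


@dataclass
class Bundle:
    """A complete simulated input bundle plus ground-truth metadata."""

    config: SimulationConfig
    expression: ExpressionMatrix
    annotations: list[GeneAnnotation]
    gene_sets: list[GeneSet]
    qtl_records: list[QTLRecord]
    comparisons: list[Comparison]
    qtl_gene_ids: frozenset[str]
    #: set_name -> {gene_id: applied log2 shift in high groups}
    applied_shifts: dict[str, dict[str, float]] = field(default_factory=dict)


def _place_qtl_intervals(cfg: SimulationConfig, rng: np.random.Generator) -> list[QTLRecord]:
    """Disjoint uniform QTL segments covering ~qtl_coverage per chromosome."""
    records: list[QTLRecord] = []
    if cfg.qtl_coverage == 0.0:
        return records
    L = cfg.chromosome_length_bp
    k = cfg.qtl_per_chromosome
    width = int(round(cfg.qtl_coverage * L / k))
    for c in range(1, cfg.chromosome_count + 1):
        free = L - k * width
        if free < 0:
            raise ValueError("qtl_coverage too large for qtl_per_chromosome")
        # uniform spacings: split the free length into k+1 gaps
        cuts = np.sort(rng.uniform(0, free, size=k)) if k > 1 else np.array([])
        gaps = np.diff(np.concatenate(([0.0], cuts, [float(free)])))
        pos = 1
        for j in range(k):
            pos += int(gaps[j])
            start = pos
            end = start + width - 1
            records.append(
                QTLRecord(
                    qtl_name=f"qtl_chr{c}_{j + 1}",
                    trait="sim",
                    chromosome=f"chr{c}",
                    peak_bp=(start + end) // 2,
                    flank_start_bp=start,
                    flank_end_bp=end,
                )
            )
            pos = end + 1
    return records


def _genes_in_qtl_mask(
    chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray, records: list[QTLRecord]
) -> np.ndarray:
    """Boolean mask of genes overlapping any QTL segment (closed intervals)."""
    mask = np.zeros(len(chroms), dtype=bool)
    by_chrom: dict[str, list[QTLRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom, recs in by_chrom.items():
        idx = np.nonzero(chroms == chrom)[0]
        if idx.size == 0:
            continue
        s, e = starts[idx], ends[idx]
        hit = np.zeros(idx.size, dtype=bool)
        for r in recs:
            hit |= (s <= r.flank_end_bp) & (e >= r.flank_start_bp)
        mask[idx] = hit
    return mask


def simulate_bundle(cfg: SimulationConfig) -> Bundle:
    """Generate a full input bundle under the configured conditions."""
    rng = np.random.default_rng(cfg.seed)

    qtl_records = _place_qtl_intervals(cfg, rng)

    # gene placement: uniform chromosome and start, fixed 10 kb length
    width = max(5, len(str(cfg.n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    chroms = rng.integers(1, cfg.chromosome_count + 1, size=cfg.n_genes)
    starts = rng.integers(1, cfg.chromosome_length_bp - GENE_LENGTH_BP + 1, size=cfg.n_genes)
    annotations = [
        GeneAnnotation(g, f"chr{c}", int(s), int(s) + GENE_LENGTH_BP - 1)
        for g, c, s in zip(gene_ids, chroms, starts)
    ]
    chrom_labels = np.array([f"chr{c}" for c in chroms], dtype=object)
    ends = starts + GENE_LENGTH_BP - 1
    in_qtl = _genes_in_qtl_mask(chrom_labels, starts, ends, qtl_records)
    gene_arr = np.array(gene_ids, dtype=object)
    qtl_gene_ids = frozenset(gene_arr[in_qtl])

    # pathway membership: spiked pathways first (controlled QTL composition),
    # then the rest from a mixed pool, all disjoint
    names = cfg.pathway_names()
    sizes = {
        n: int(s)
        for n, s in zip(
            names,
            rng.integers(
                cfg.pathway_size_range[0], cfg.pathway_size_range[1] + 1, size=cfg.n_pathways
            ),
        )
    }
    in_pool = list(rng.permutation(gene_arr[in_qtl]))
    out_pool = list(rng.permutation(gene_arr[~in_qtl]))
    members_by_name: dict[str, tuple[str, ...]] = {}
    for spike in cfg.spiked_pathways:
        size = sizes[spike.set_name]
        n_in = int(round(spike.fraction_in_qtl * size))
        if n_in > len(in_pool) or size - n_in > len(out_pool):
            raise ValueError(
                f"cannot place spiked pathway {spike.set_name!r}: pool exhausted "
                f"(need {n_in} in-QTL, {size - n_in} out-of-QTL genes)"
            )
        chosen = [in_pool.pop() for _ in range(n_in)]
        chosen += [out_pool.pop() for _ in range(size - n_in)]
        members_by_name[spike.set_name] = tuple(sorted(chosen))
    mixed_pool = list(rng.permutation(np.array(in_pool + out_pool, dtype=object)))
    for name in names:
        if name in members_by_name:
            continue
        size = sizes[name]
        if size > len(mixed_pool):
            raise ValueError("gene pool exhausted while building pathways")
        members_by_name[name] = tuple(sorted(mixed_pool[:size]))
        del mixed_pool[:size]
    gene_sets = [GeneSet(n, "Simulated", members_by_name[n]) for n in names]

    # expression: baseline per gene + optional shared factor + iid noise
    sample_ids = [
        f"{g}_r{j + 1}" for g in cfg.groups for j in range(cfg.n_samples_per_group)
    ]
    sample_groups = {
        s: g for g in cfg.groups for s in [f"{g}_r{j + 1}" for j in range(cfg.n_samples_per_group)]
    }
    n_samples = len(sample_ids)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    if cfg.equicorrelation > 0:
        values += rng.normal(0.0, cfg.equicorrelation, size=n_samples)[None, :]

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    high_cols = [
        j for j, s in enumerate(sample_ids) if sample_groups[s] in cfg.high_groups
    ]
    applied_shifts: dict[str, dict[str, float]] = {}
    for spike in cfg.spiked_pathways:
        members = members_by_name[spike.set_name]
        targets = [g for g in members if g in qtl_gene_ids]
        shifts: dict[str, float] = {}
        for g in targets:
            if spike.mode == "U":
                shift = spike.effect_size
            elif spike.mode == "D":
                shift = -spike.effect_size
            else:  # B: random sign per gene
                shift = float(rng.choice([-1.0, 1.0])) * spike.effect_size
            values[gene_pos[g], high_cols] += shift
            shifts[g] = shift
        applied_shifts[spike.set_name] = shifts

    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), sample_groups
    )
    return Bundle(
        config=cfg,
        expression=expression,
        annotations=annotations,
        gene_sets=gene_sets,
        qtl_records=qtl_records,
        comparisons=cfg.comparisons(),
        qtl_gene_ids=qtl_gene_ids,
        applied_shifts=applied_shifts,
    )


def null_bundle(cfg: SimulationConfig) -> Bundle:
    """The same bundle with every effect size forced to zero (global null)."""
    return simulate_bundle(replace(cfg, spiked_pathways=()))


def truth_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-pathway ground truth: spiked flag, mode and expected direction."""
    spike_by_name = {s.set_name: s for s in cfg.spiked_pathways}
    rows = []
    for name in cfg.pathway_names():
        spike = spike_by_name.get(name)
        rows.append(
            {
                "set_name": name,
                "spiked": spike is not None,
                "mode": spike.mode if spike else "",
                "effect_size": spike.effect_size if spike else 0.0,
                "expected_direction": spike.mode if spike else "",
            }
        )
    return pd.DataFrame(rows)


def spiked_config(
    seed: int = 0,
    effect_size: float = 1.0,
    n_in_qtl: int = 20,
    pathway_size: int = 40,
    mode: str = "U",
    **overrides,
) -> SimulationConfig:
    """The spike-in recovery scenario: one pathway with ``n_in_qtl`` of its
    ``pathway_size`` members inside QTL regions carrying the effect."""
    cfg = SimulationConfig(
        pathway_size_range=(pathway_size, pathway_size),
        spiked_pathways=(
            SpikeSpec("pw001", mode=mode, effect_size=effect_size,
                      fraction_in_qtl=n_in_qtl / pathway_size),
        ),
        seed=seed,
        **overrides,
    )
    return cfg


def write_bundle(bundle: Bundle, out_dir) -> dict[str, Path]:
    """Write the bundle in the package's file dialects; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "groups": out / "groups.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "annotations": out / "annotations.tsv",
        "qtl": out / "qtl.tsv",
        "truth": out / "truth.tsv",
    }
    io_formats.write_expression(bundle.expression, paths["expression"], paths["groups"])
    io_formats.write_gmt(bundle.gene_sets, paths["gene_sets"])
    io_formats.write_gene_annotations(bundle.annotations, paths["annotations"])
    io_formats.write_qtl_table(bundle.qtl_records, paths["qtl"])
    truth_table(bundle.config).to_csv(paths["truth"], sep="\t", index=False)
    return paths
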