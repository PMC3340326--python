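"""End-to-end run: config -> preprocessing -> Q -> set tests -> results files.

`run_pipeline` wires the modules together, writes the results table,
per-comparison intermediate tables, the sorted-p-value diagnostic table and
a JSON run manifest recording every parameter, input checksums and the
counts at each filtering step.  Runs are fully deterministic: identical
config and inputs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import gsa_core, intersect_test, io_formats, preprocess, qtl_map
from .gsa_core import Comparison
from .intersect_test import TestConfig
from .io_formats import IntersectionResult

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid or references missing files."""


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    All thresholds default to the method's standard values: alpha 0.05,
    set size 10-500, peak +/- 20 Mb fallback intervals, ``AFFX-`` control
    prefix, ``Human Diseases`` category dropped.
    """

    expression_path: str
    groups_path: str
    gene_sets_path: str
    annotations_path: str
    qtl_path: str
    comparisons: list[dict]  # each: {name, high, low}
    output_dir: str = "qtlgsa_out"
    trait: str | None = None
    probe_gene_map_path: str | None = None
    replicate_map_path: str | None = None
    control_prefix: str = preprocess.DEFAULT_CONTROL_PREFIX
    filter_controls: bool = True
    min_set_size: int = preprocess.DEFAULT_MIN_SET_SIZE
    max_set_size: int = preprocess.DEFAULT_MAX_SET_SIZE
    drop_categories: list[str] = field(
        default_factory=lambda: sorted(preprocess.DEFAULT_DROP_CATEGORIES)
    )
    alpha: float = 0.05
    min_intersection: int = intersect_test.DEFAULT_MIN_INTERSECTION
    modes: list[str] = field(default_factory=lambda: ["U", "D", "B"])
    count_dropped_in_m: bool = False
    fallback_halfwidth_bp: int = qtl_map.DEFAULT_FALLBACK_HALFWIDTH_BP
    input_scale: str = "log2"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        missing = {
            "expression_path", "groups_path", "gene_sets_path",
            "annotations_path", "qtl_path", "comparisons",
        } - set(raw)
        if missing:
            raise ConfigError(f"{path}: missing required key(s) {sorted(missing)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.comparisons:
            raise ConfigError("comparisons must be non-empty")
        for c in self.comparisons:
            if not {"name", "high", "low"} <= set(c):
                raise ConfigError(f"comparison entry needs name/high/low: {c}")
        for p in self.input_paths().values():
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    def input_paths(self) -> dict[str, str | None]:
        return {
            "expression": self.expression_path,
            "groups": self.groups_path,
            "gene_sets": self.gene_sets_path,
            "annotations": self.annotations_path,
            "qtl": self.qtl_path,
            "probe_gene_map": self.probe_gene_map_path,
            "replicate_map": self.replicate_map_path,
        }

    def comparison_objects(self) -> list[Comparison]:
        return [Comparison(c["name"], c["high"], c["low"]) for c in self.comparisons]

    def test_config(self) -> TestConfig:
        return TestConfig(
            alpha=self.alpha,
            min_intersection=self.min_intersection,
            modes=tuple(self.modes),
            count_dropped_in_m=self.count_dropped_in_m,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> list[IntersectionResult]:
    """Execute the full analysis described by ``cfg`` and write outputs.

    Writes into ``cfg.output_dir``: ``results.tsv``, per-comparison
    ``gene_stats__<cmp>.tsv``, ``set_scores.tsv``, ``sorted_pvalues.tsv``
    and ``manifest.json``.
    """
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    expr = io_formats.read_expression(cfg.expression_path, cfg.groups_path)
    gene_sets = io_formats.read_gmt(cfg.gene_sets_path)
    annotations = io_formats.read_gene_annotations(cfg.annotations_path)
    qtl_records = io_formats.read_qtl_table(cfg.qtl_path)

    counts = {"n_features_input": expr.n_features, "n_samples_input": expr.n_samples}

    if cfg.filter_controls:
        expr = preprocess.filter_control_probes(expr, cfg.control_prefix)
    counts["n_features_after_control_filter"] = expr.n_features

    if cfg.replicate_map_path:
        rep_df = pd.read_csv(cfg.replicate_map_path, sep="\t", dtype=str)
        if not {"sample_id", "array_group"} <= set(rep_df.columns):
            raise ConfigError(
                f"{cfg.replicate_map_path}: expected columns 'sample_id' and 'array_group'"
            )
        expr = preprocess.merge_replicates(
            expr, dict(zip(rep_df["sample_id"], rep_df["array_group"]))
        )
    counts["n_samples_after_merge"] = expr.n_samples

    if cfg.probe_gene_map_path:
        probe_map = io_formats.read_probe_gene_map(cfg.probe_gene_map_path)
        expr = preprocess.collapse_probes_to_genes(expr, probe_map)
    counts["n_genes_measured"] = expr.n_features

    universe = expr.feature_ids
    counts["n_gene_sets_input"] = len(gene_sets)
    gene_sets = preprocess.filter_gene_sets(
        gene_sets, universe, cfg.min_set_size, cfg.max_set_size, cfg.drop_categories
    )
    counts["n_gene_sets_retained"] = len(gene_sets)

    intervals = qtl_map.build_qtl_intervals(
        qtl_records, trait=cfg.trait, fallback_halfwidth_bp=cfg.fallback_halfwidth_bp
    )
    counts["n_qtl_intervals"] = len(intervals)
    q = qtl_map.genes_in_qtl(annotations, intervals)
    counts["n_genes_in_qtl"] = len(q)
    counts["n_qtl_genes_measured"] = len(q & set(universe))

    comparisons = cfg.comparison_objects()
    test_cfg = cfg.test_config()
    pairs = intersect_test.intersect_sets(gene_sets, q, universe, test_cfg.min_intersection)
    results = intersect_test.run_analysis(
        expr, comparisons, gene_sets, q, test_cfg,
        input_scale=cfg.input_scale, pairs=pairs,
    )
    counts["m"] = (
        counts["n_gene_sets_retained"] if cfg.count_dropped_in_m else len(pairs)
    )
    counts["n_significant"] = sum(r.significant for r in results)

    cmp_names = [c.name for c in comparisons]
    io_formats.write_results(results, out_dir / "results.tsv", comparisons=cmp_names)

    # intermediate tables: per-comparison gene statistics and set scores
    stats_by_cmp = gsa_core.gene_stats_for_modes(
        expr, comparisons, test_cfg.modes, input_scale=cfg.input_scale
    )
    for cmp in comparisons:
        tbl = pd.DataFrame({"gene_id": universe})
        for stat_mode, gs in sorted(stats_by_cmp[cmp.name].items()):
            tbl[f"fc_{stat_mode}"] = gs.values.to_numpy()
        tbl.to_csv(out_dir / f"gene_stats__{cmp.name}.tsv", sep="\t", index=False)

    score_rows = []
    for cmp in comparisons:
        for mode in test_cfg.modes:
            stat_mode, tail = gsa_core.MODE_VARIANTS[mode]
            gs_stats = stats_by_cmp[cmp.name][stat_mode]
            for pair in pairs:
                for kind, members in (
                    ("sub", pair.sub_members),
                    ("whole", pair.gene_set.members),
                ):
                    sc = gsa_core.set_zscore(gs_stats, members, pair.gene_set.set_name)
                    score_rows.append(
                        {
                            "comparison": cmp.name,
                            "mode": mode,
                            "set_name": pair.gene_set.set_name,
                            "kind": kind,
                            "n": sc.n,
                            "x": sc.x,
                            "mu": sc.mu,
                            "sigma": sc.sigma,
                            "z": sc.z,
                            "p": gsa_core.zscore_pvalue(sc, tail),
                        }
                    )
    pd.DataFrame(score_rows).to_csv(out_dir / "set_scores.tsv", sep="\t", index=False)

    if results:
        intersect_test.sorted_pvalue_table(results).to_csv(
            out_dir / "sorted_pvalues.tsv", sep="\t", index=False
        )

    manifest = {
        "package": "qtlgsa",
        "config": dataclasses.asdict(cfg),
        "input_sha256": {
            k: (_sha256(p) if p else None) for k, p in cfg.input_paths().items()
        },
        "counts": counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote results for %d pathway(s) to %s", len(results), out_dir)
    return results


def evaluate_bundle(
    bundle,
    test_cfg: TestConfig = TestConfig(),
    min_set_size: int = preprocess.DEFAULT_MIN_SET_SIZE,
    max_set_size: int = preprocess.DEFAULT_MAX_SET_SIZE,
    input_scale: str = "log2",
) -> list[IntersectionResult]:
    """Run the analysis on an in-memory synthetic bundle (no file IO).

    Same computational path as `run_pipeline`: gene-set filtering, QTL
    interval construction, Q, and the intersection significance procedure.
    """
    expr = bundle.expression
    gene_sets = preprocess.filter_gene_sets(
        bundle.gene_sets, expr.feature_ids, min_set_size, max_set_size
    )
    intervals = qtl_map.build_qtl_intervals(bundle.qtl_records)
    q = qtl_map.genes_in_qtl(bundle.annotations, intervals)
    return intersect_test.run_analysis(
        expr, bundle.comparisons, gene_sets, q, test_cfg, input_scale=input_scale
    )


def plot_sorted_pvalues(results: Sequence[IntersectionResult], path) -> None:
    """Scatter of sorted combined maximum p-values with sub/whole colouring.

    Red points mark pathways whose QTL sub-set is more significant than the
    whole pathway, blue the converse; the diagonal is the expected pattern
    under a uniform p-value distribution.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no results to plot")
    tbl = intersect_test.sorted_pvalue_table(results)
    m = len(tbl)
    colors = np.where(tbl["smaller"] == "sub", "red", "blue")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(tbl["rank"], tbl["max_sub_p"], c=colors, s=14)
    ax.plot([1, m], [1 / m, 1.0], color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("rank of gene set")
    ax.set_ylabel("maximum sub-set p-value across comparisons")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "qtlgsa"})
    plt.close(fig)
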