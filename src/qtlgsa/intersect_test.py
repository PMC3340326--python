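"""Significance of QTL-intersection sub-pathways with an FDR criterion.

For each pathway Gi (of m retained pathways) and the trait's QTL gene set
Q, the sub-set Gi ∩ Q is scored alongside the whole measured pathway.  The
sub-set p-values are sorted ascending and the pathway at rank i is called
significant iff

    P(Gi ∩ Q) < min{ P(Gi), i * alpha / m }

i.e. it must clear the rank's Benjamini-Hochberg critical value *and* be
more significant than its own whole pathway.  The criterion is applied per
rank as displayed (not as a step-up over the largest passing rank), so the
discovery set is always a subset of the plain BH step-up discoveries at the
same alpha.

Evidence is combined across strain comparisons by the maximum p-value: a
pathway is significant overall iff the procedure passes on the per-pathway
maximum sub-set and whole-pathway p-values *and* the pathway is flagged in
every individual comparison.  When several direction variants (U/D/B) are
run, each variant is a separate run of the procedure with the same m and a
pathway significant in at least one variant is reported once, labelled by
the most significant passing variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import gsa_core
from .gsa_core import MODE_VARIANTS, Comparison
from .io_formats import ExpressionMatrix, GeneSet, IntersectionResult

logger = logging.getLogger(__name__)

#: default lower bound on the QTL sub-set size.  The 10-gene minimum that
#: bounds whole pathway sets is applied to the intersections Gi ∩ Q as
#: well: a z-score on the mean of fewer than ~10 (absolute) fold changes
#: leans too hard on the central limit theorem, and real analyses report
#: no intersections below 10.  Set to 1 to keep every non-empty sub-set.
DEFAULT_MIN_INTERSECTION = 10


@dataclass(frozen=True)
class TestConfig:
    """Knobs of the significance procedure.

    alpha:
        target false discovery rate of the experiment.
    min_intersection:
        smallest sub-set size kept; pathways with fewer QTL genes are
        dropped before ranking (and do not count toward m by default).
    modes:
        direction variants to run, subset of {"U", "D", "B"}.
    count_dropped_in_m:
        if True, m counts pathways before dropping empty/small
        intersections (the alternative reading of m).
    """

    __test__ = False  # not a pytest test class

    alpha: float = 0.05
    min_intersection: int = DEFAULT_MIN_INTERSECTION
    modes: tuple[str, ...] = ("U", "D", "B")
    count_dropped_in_m: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_intersection < 1:
            raise ValueError("min_intersection must be >= 1")
        unknown = set(self.modes) - set(MODE_VARIANTS)
        if unknown:
            raise ValueError(f"unknown mode(s) {sorted(unknown)}")
        if not self.modes:
            raise ValueError("at least one mode required")


@dataclass
class IntersectionPair:
    """A measured pathway and its QTL sub-set."""

    gene_set: GeneSet  # membership already restricted to the universe
    sub_members: frozenset[str]


@dataclass
class StepResult:
    """Output of one significance step, aligned to the input pathway order."""

    flags: np.ndarray  # bool
    rank: np.ndarray  # int, 1..m
    critical_value: np.ndarray  # float, rank * alpha / m


@dataclass
class CombinedSignificance:
    """One direction variant combined across comparisons (input order)."""

    max_sub_p: np.ndarray
    max_whole_p: np.ndarray
    combined: StepResult  # significance step on the maximum p-values
    per_comparison_flags: dict[str, np.ndarray]
    overall: np.ndarray  # combined flag AND flagged in every comparison


def intersect_sets(
    pathways: Sequence[GeneSet],
    qtl_genes: Iterable[str],
    universe: Iterable[str],
    min_intersection: int = DEFAULT_MIN_INTERSECTION,
) -> list[IntersectionPair]:
    """Pair each pathway with its sub-set ``members ∩ Q ∩ universe``.

    Pathways whose sub-set is smaller than ``min_intersection`` are dropped
    with a logged count; the retained count is m.
    """
    universe_set = set(universe)
    q = set(qtl_genes) & universe_set
    if not q:
        raise ValueError("no QTL genes among the measured genes (Q ∩ universe empty)")
    pairs: list[IntersectionPair] = []
    n_dropped = 0
    for gs in pathways:
        measured = tuple(g for g in gs.members if g in universe_set)
        sub = frozenset(g for g in measured if g in q)
        if len(sub) < min_intersection:
            n_dropped += 1
            continue
        pairs.append(IntersectionPair(GeneSet(gs.set_name, gs.category, measured), sub))
    if n_dropped:
        logger.info(
            "dropped %d pathway(s) with QTL intersection < %d", n_dropped, min_intersection
        )
    return pairs


def bh_critical_value(i: int, m: int, alpha: float) -> float:
    """Benjamini-Hochberg critical value i*alpha/m for rank i of m."""
    if not 1 <= i <= m:
        raise ValueError(f"rank i={i} outside 1..{m}")
    return i * alpha / m


def significance_step(
    sub_p: Sequence[float],
    whole_p: Sequence[float],
    cfg: TestConfig,
    set_names: Sequence[str] | None = None,
    m: int | None = None,
) -> StepResult:
    """Apply the per-rank criterion sub_p(i) < min(whole_p(i), i*alpha/m).

    Sorting by sub-set p-value happens internally (ties broken by whole
    p-value, then set name, so ranks are deterministic); outputs are
    aligned back to the input order.  ``m`` defaults to the number of
    pathways supplied.
    """
    sub = np.asarray(sub_p, dtype=float)
    whole = np.asarray(whole_p, dtype=float)
    if sub.shape != whole.shape:
        raise ValueError(
            f"sub_p and whole_p length mismatch: {sub.shape} vs {whole.shape}"
        )
    n = sub.size
    if m is None:
        m = n
    names = np.asarray(set_names if set_names is not None else [""] * n, dtype=object)
    # np.lexsort sorts by the last key first
    order = np.lexsort((names, whole, sub))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    critical = rank * cfg.alpha / m
    flags = sub < np.minimum(whole, critical)
    return StepResult(flags=flags, rank=rank, critical_value=critical)


def combine_comparisons(
    per_comparison: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    cfg: TestConfig,
    set_names: Sequence[str] | None = None,
    m: int | None = None,
) -> CombinedSignificance:
    """Combine one variant's evidence across comparisons by maximum p-value.

    ``per_comparison`` maps comparison name -> (sub_p, whole_p, flags), all
    aligned to one pathway order.  Overall significance requires the
    significance step to pass on the maxima AND the pathway to be flagged
    in every comparison.
    """
    if not per_comparison:
        raise ValueError("at least one comparison required")
    lengths = {len(sub) for sub, _, _ in per_comparison.values()}
    if len(lengths) != 1:
        raise ValueError("pathway universes differ across comparisons")
    subs = np.vstack([np.asarray(s, dtype=float) for s, _, _ in per_comparison.values()])
    wholes = np.vstack([np.asarray(w, dtype=float) for _, w, _ in per_comparison.values()])
    flags = np.vstack([np.asarray(f, dtype=bool) for _, _, f in per_comparison.values()])
    max_sub = subs.max(axis=0)
    max_whole = wholes.max(axis=0)
    combined = significance_step(max_sub, max_whole, cfg, set_names=set_names, m=m)
    overall = combined.flags & flags.all(axis=0)
    return CombinedSignificance(
        max_sub_p=max_sub,
        max_whole_p=max_whole,
        combined=combined,
        per_comparison_flags={c: flags[i] for i, c in enumerate(per_comparison)},
        overall=overall,
    )


def sorted_pvalue_table(results: Sequence[IntersectionResult]):
    """Plot-ready table of sorted combined p-values.

    Rows sorted by max_sub_p ascending; ``smaller`` flags whether the
    sub-pathway or the whole pathway is the more significant (ties go to
    ``whole``).
    """
    import pandas as pd

    if not results:
        raise ValueError("no results to tabulate")
    ordered = sorted(results, key=lambda r: (r.max_sub_p, r.set_name))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "set_name": [r.set_name for r in ordered],
            "max_sub_p": [r.max_sub_p for r in ordered],
            "max_whole_p": [r.max_whole_p for r in ordered],
            "smaller": [
                "sub" if r.max_sub_p < r.max_whole_p else "whole" for r in ordered
            ],
        }
    )


def run_analysis(
    expr: ExpressionMatrix,
    comparisons: Sequence[Comparison],
    pathways: Sequence[GeneSet],
    qtl_genes: Iterable[str],
    cfg: TestConfig = TestConfig(),
    input_scale: str = "log2",
    pairs: list[IntersectionPair] | None = None,
) -> list[IntersectionResult]:
    """Run the full intersection-set procedure and assemble results.

    For every direction variant in ``cfg.modes`` and every comparison the
    sub-set and whole-pathway p-values are computed, the per-rank criterion
    applied, and evidence combined across comparisons; each pathway is then
    reported once with the values of its most significant variant.
    ``pairs`` may carry precomputed pathway/sub-set pairs.
    """
    universe = expr.feature_ids
    if pairs is None:
        pairs = intersect_sets(pathways, qtl_genes, universe, cfg.min_intersection)
    if not pairs:
        return []
    m = len(pathways) if cfg.count_dropped_in_m else len(pairs)
    names = [p.gene_set.set_name for p in pairs]

    stats_by_cmp = gsa_core.gene_stats_for_modes(
        expr, comparisons, cfg.modes, input_scale=input_scale
    )

    # z-scores are shared by variants using the same statistic (U and D)
    z_cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for stat_mode in {MODE_VARIANTS[m_][0] for m_ in cfg.modes}:
        for cmp in comparisons:
            gene_stats = stats_by_cmp[cmp.name][stat_mode]
            sub_z = np.empty(len(pairs))
            whole_z = np.empty(len(pairs))
            for k, pair in enumerate(pairs):
                sub_z[k] = gsa_core.set_zscore(
                    gene_stats, pair.sub_members, set_name=pair.gene_set.set_name
                ).z
                whole_z[k] = gsa_core.set_zscore(
                    gene_stats, pair.gene_set.members, set_name=pair.gene_set.set_name
                ).z
            z_cache[(stat_mode, cmp.name)] = (sub_z, whole_z)

    # p-value matrices per mode: {mode: {cmp: (sub_p, whole_p)}}
    pvals: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for mode in cfg.modes:
        stat_mode, tail = MODE_VARIANTS[mode]
        pvals[mode] = {}
        for cmp in comparisons:
            sub_z, whole_z = z_cache[(stat_mode, cmp.name)]
            sub_p = np.array([gsa_core.zscore_pvalue(z, tail) for z in sub_z])
            whole_p = np.array([gsa_core.zscore_pvalue(z, tail) for z in whole_z])
            pvals[mode][cmp.name] = (sub_p, whole_p)

    combined_by_mode: dict[str, CombinedSignificance] = {}
    for mode in cfg.modes:
        per_cmp = {}
        for cmp in comparisons:
            sub_p, whole_p = pvals[mode][cmp.name]
            step = significance_step(sub_p, whole_p, cfg, set_names=names, m=m)
            per_cmp[cmp.name] = (sub_p, whole_p, step.flags)
        combined_by_mode[mode] = combine_comparisons(per_cmp, cfg, set_names=names, m=m)

    results: list[IntersectionResult] = []
    for k, pair in enumerate(pairs):
        p_by_mode = {mode: combined_by_mode[mode].max_sub_p[k] for mode in cfg.modes}
        passed = {mode: bool(combined_by_mode[mode].overall[k]) for mode in cfg.modes}
        significant = any(passed.values())
        if significant:
            label = gsa_core.direction_label(p_by_mode, passed)
        else:
            # report the most significant variant even when nothing passes
            label = min(
                cfg.modes, key=lambda mde: (p_by_mode[mde], gsa_core._LABEL_PRECEDENCE[mde])
            )
        comb = combined_by_mode[label]
        results.append(
            IntersectionResult(
                set_name=pair.gene_set.set_name,
                category=pair.gene_set.category,
                n_genes=len(pair.gene_set.members),
                n_in_qtl=len(pair.sub_members),
                direction=label,
                max_sub_p=float(comb.max_sub_p[k]),
                max_whole_p=float(comb.max_whole_p[k]),
                rank=int(comb.combined.rank[k]),
                critical_value=float(comb.combined.critical_value[k]),
                significant=significant,
                sub_p={c.name: float(pvals[label][c.name][0][k]) for c in comparisons},
                whole_p={c.name: float(pvals[label][c.name][1][k]) for c in comparisons},
            )
        )
    n_sig = sum(r.significant for r in results)
    logger.info("m=%d retained pathway(s), %d significant", m, n_sig)
    return results
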