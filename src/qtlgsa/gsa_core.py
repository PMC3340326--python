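"""Gene-level fold-change statistics and the z-score gene set statistic.

The gene-level statistic for a two-group (high vs low strain) comparison is
the log2 fold change.  For a gene set the statistic is the standardized set
mean under the competitive null (members drawn from the array background):

    z = (x - mu) / sqrt(sigma^2 / n)

where mu and sigma are the mean and population standard deviation of the
(absolute) fold changes of *all* measured genes, and x and n are the mean
and count over the set's measured members.  P-values come from the standard
normal.

Three direction variants are evaluated per set:

* ``U`` — signed fold changes, upper tail (coordinated up-regulation);
* ``D`` — signed fold changes, lower tail (coordinated down-regulation);
* ``B`` — absolute fold changes, upper tail (bi-directional change: the
  set's mean magnitude of change exceeds background).

The background mu, sigma are computed per variant's statistic (signed
background for U/D, absolute background for B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io_formats import ExpressionMatrix

#: direction variants and the (statistic mode, normal tail) each one uses
MODE_VARIANTS: dict[str, tuple[str, str]] = {
    "U": ("signed", "upper"),
    "D": ("signed", "lower"),
    "B": ("absolute", "upper"),
}

#: tie-break precedence for direction labels: a signed call is more
#: informative than the bi-directional one
_LABEL_PRECEDENCE = {"U": 0, "D": 1, "B": 2}


@dataclass(frozen=True)
class Comparison:
    """A two-class unpaired strain comparison: high-phenotype vs low."""

    name: str
    group_high: str
    group_low: str

    def __post_init__(self):
        if self.group_high == self.group_low:
            raise ValueError(f"comparison {self.name!r}: identical groups")


@dataclass
class GeneStats:
    """Per-gene statistics for one comparison (signed or absolute)."""

    comparison: str
    values: pd.Series  # gene_id -> statistic
    mode: str  # "signed" | "absolute"

    def __post_init__(self):
        if self.mode not in ("signed", "absolute"):
            raise ValueError(f"unknown mode {self.mode!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError(f"comparison {self.comparison!r}: non-finite gene statistic")
        if self.mode == "absolute" and arr.size and (arr < 0).any():
            raise ValueError("absolute-mode statistics must be non-negative")
        self._background: tuple[float, float] | None = None

    def background(self) -> tuple[float, float]:
        """(mu, sigma) over all measured genes; sigma is population SD."""
        if self._background is None:
            arr = self.values.to_numpy(dtype=float)
            self._background = (float(arr.mean()), float(arr.std(ddof=0)))
        return self._background


@dataclass(frozen=True)
class SetScore:
    """z-score of a gene set against the array background.

    Recomputing ``(x - mu) / sqrt(sigma**2 / n)`` from the stored fields
    reproduces ``z`` exactly.
    """

    set_name: str
    mode: str
    z: float
    n: int
    x: float
    mu: float
    sigma: float


def log2_fold_change(
    expr: ExpressionMatrix, cmp: Comparison, input_scale: str = "log2"
) -> GeneStats:
    """Per-gene log2 fold change between the comparison's group means.

    With ``input_scale="log2"`` (RMA-style inputs) this is the difference of
    log2-scale group means, i.e. the log-ratio of geometric means.  With
    ``input_scale="linear"`` it is log2 of the ratio of linear-scale means
    (all group means must be positive).
    """
    high = expr.samples_in_group(cmp.group_high)
    low = expr.samples_in_group(cmp.group_low)
    if not high:
        raise ValueError(f"comparison {cmp.name!r}: group {cmp.group_high!r} has no samples")
    if not low:
        raise ValueError(f"comparison {cmp.name!r}: group {cmp.group_low!r} has no samples")
    mean_high = expr.values[high].mean(axis=1)
    mean_low = expr.values[low].mean(axis=1)
    if input_scale == "log2":
        fc = mean_high - mean_low
    elif input_scale == "linear":
        if (mean_high <= 0).any() or (mean_low <= 0).any():
            raise ValueError("linear-scale fold change requires positive group means")
        fc = np.log2(mean_high / mean_low)
    else:
        raise ValueError(f"unknown input_scale {input_scale!r}")
    return GeneStats(cmp.name, fc, "signed")


def to_absolute(gene_stats: GeneStats) -> GeneStats:
    """Replace each statistic by its absolute value (bi-directional mode).

    Idempotent: absolute-mode input is returned unchanged.
    """
    return GeneStats(gene_stats.comparison, gene_stats.values.abs(), "absolute")


def set_zscore(
    gene_stats: GeneStats,
    members: Iterable[str],
    set_name: str = "",
    background: tuple[float, float] | None = None,
) -> SetScore:
    """z-score of ``members`` against the all-genes background.

    mu and sigma are the mean and population (divide-by-N) standard
    deviation of every measured gene's statistic; x and n are taken over
    the measured members.  ``background`` overrides (mu, sigma), e.g. to
    hold the reference distribution fixed.
    """
    values = gene_stats.values
    unique_members = list(dict.fromkeys(members))
    member_vals = values.reindex(unique_members).dropna()
    n = len(member_vals)
    if n == 0:
        raise ValueError(f"gene set {set_name!r}: no members among measured genes")
    if len(values) < 2:
        raise ValueError("background needs at least 2 measured genes")
    mu, sigma = background if background is not None else gene_stats.background()
    if sigma == 0.0:
        raise ValueError("degenerate background: zero standard deviation")
    x = float(member_vals.to_numpy(dtype=float).mean())
    z = (x - mu) / np.sqrt(sigma**2 / n)
    return SetScore(set_name, gene_stats.mode, float(z), n, x, mu, sigma)


def zscore_pvalue(score: SetScore | float, tail: str = "upper") -> float:
    """Standard-normal tail probability of a set z-score.

    ``upper`` = P(Z >= z), ``lower`` = P(Z <= z),
    ``two_sided`` = 2 P(Z >= |z|), capped at 1.
    """
    z = score.z if isinstance(score, SetScore) else float(score)
    if tail == "upper":
        return float(_stats.norm.sf(z))
    if tail == "lower":
        return float(_stats.norm.cdf(z))
    if tail == "two_sided":
        return float(min(1.0, 2.0 * _stats.norm.sf(abs(z))))
    raise ValueError(f"unknown tail {tail!r}")


def direction_label(
    p_by_mode: Mapping[str, float], passed_by_mode: Mapping[str, bool]
) -> str:
    """Pick the direction label U/D/B for a significant pathway.

    Among the variants that passed the significance criterion, the one with
    the smallest combined p-value wins; exact ties prefer a signed call
    (U, then D) over the bi-directional B.
    """
    candidates = [m for m, ok in passed_by_mode.items() if ok]
    if not candidates:
        raise ValueError("direction_label called on a non-significant pathway")
    return min(candidates, key=lambda m: (p_by_mode[m], _LABEL_PRECEDENCE[m]))


def gene_stats_for_modes(
    expr: ExpressionMatrix,
    comparisons: Sequence[Comparison],
    modes: Sequence[str],
    input_scale: str = "log2",
) -> dict[str, dict[str, GeneStats]]:
    """Compute, per comparison, the signed/absolute statistics the modes need.

    Returns ``{comparison name: {"signed": ..., "absolute": ...}}`` with only
    the statistic modes actually required.
    """
    need = {MODE_VARIANTS[m][0] for m in modes}
    out: dict[str, dict[str, GeneStats]] = {}
    for cmp in comparisons:
        signed = log2_fold_change(expr, cmp, input_scale=input_scale)
        per = {}
        if "signed" in need:
            per["signed"] = signed
        if "absolute" in need:
            per["absolute"] = to_absolute(signed)
        out[cmp.name] = per
    return out
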