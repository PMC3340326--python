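"""Probe-level preprocessing and gene-set filtering.

Turns replicate probe-level arrays into the single gene-level matrix the
analysis consumes:

1. drop array control probe sets (ids starting ``AFFX-`` by default);
2. average technical replicates of the same array group;
3. collapse probe sets to genes, keeping for each gene the probe set with
   the largest mean expression across all samples (one real measured probe
   profile per gene — values are never mixed across probes);
4. restrict pathway gene sets to the measured universe and keep those with
   10-500 measured members, dropping unwanted categories (default
   ``Human Diseases``).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import ExpressionMatrix, FormatError, GeneSet

logger = logging.getLogger(__name__)

DEFAULT_CONTROL_PREFIX = "AFFX-"
DEFAULT_MIN_SET_SIZE = 10
DEFAULT_MAX_SET_SIZE = 500
DEFAULT_DROP_CATEGORIES = frozenset({"Human Diseases"})


def filter_control_probes(
    expr: ExpressionMatrix, control_prefix: str = DEFAULT_CONTROL_PREFIX
) -> ExpressionMatrix:
    """Remove hybridization-control features whose id starts with the prefix.

    Survivor order is preserved; removing every feature yields an empty
    matrix, which is allowed.
    """
    keep = [f for f in expr.feature_ids if not f.startswith(control_prefix)]
    n_removed = expr.n_features - len(keep)
    if n_removed:
        logger.info("removed %d control feature(s) with prefix %r", n_removed, control_prefix)
    return ExpressionMatrix(expr.values.loc[keep], expr.sample_groups)


def merge_replicates(
    expr: ExpressionMatrix, replicate_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Average technical replicates into one column per array group.

    ``replicate_map`` assigns every sample id to an array group (e.g. the
    triplicate arrays of one strain).  The merged column carries the group
    label of its replicates, which must agree.
    """
    missing = [s for s in expr.sample_ids if s not in replicate_map]
    if missing:
        raise FormatError(f"sample {missing[0]!r} absent from replicate map")

    order: list[str] = []
    members: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        g = replicate_map[s]
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(s)
    for g, samples in members.items():
        if not samples:
            raise FormatError(f"replicate group {g!r} is empty")
        labels = {expr.sample_groups[s] for s in samples}
        if len(labels) > 1:
            raise FormatError(
                f"replicate group {g!r} mixes sample groups {sorted(labels)}"
            )

    merged = pd.DataFrame(
        {g: expr.values[members[g]].mean(axis=1) for g in order}, index=expr.values.index
    )
    groups = {g: expr.sample_groups[members[g][0]] for g in order}
    return ExpressionMatrix(merged, groups)


def collapse_probes_to_genes(
    expr: ExpressionMatrix, probe_gene_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Keep one probe set per gene: the one with the largest mean expression.

    The retained row is verbatim one of the gene's probe rows, relabeled
    with the gene id; ties go to the lexicographically smallest probe id.
    Features absent from the map are dropped with a logged count.  Output
    rows are ordered by gene id for determinism.
    """
    mapped = [f for f in expr.feature_ids if f in probe_gene_map]
    n_unmapped = expr.n_features - len(mapped)
    if n_unmapped:
        logger.info("dropped %d unmapped probe set(s)", n_unmapped)

    row_means = expr.values.loc[mapped].mean(axis=1)
    best: dict[str, str] = {}
    for probe in mapped:
        gene = probe_gene_map[probe]
        cur = best.get(gene)
        if cur is None:
            best[gene] = probe
            continue
        # higher mean wins; on an exact tie the smaller probe_id wins
        if (row_means[probe], cur) > (row_means[cur], probe):
            best[gene] = probe

    genes = sorted(best)
    out = expr.values.loc[[best[g] for g in genes]]
    out.index = pd.Index(genes)
    return ExpressionMatrix(out, expr.sample_groups)


def filter_gene_sets(
    sets: Iterable[GeneSet],
    universe: Iterable[str],
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
    drop_categories: Iterable[str] = DEFAULT_DROP_CATEGORIES,
) -> list[GeneSet]:
    """Restrict sets to measured genes and apply size and category bounds.

    Membership is intersected with ``universe`` first, so the size bound
    counts measured genes only.  Idempotent.
    """
    if min_size > max_size:
        raise ValueError(f"min_size ({min_size}) > max_size ({max_size})")
    universe_set = set(universe)
    dropped = set(drop_categories)
    out: list[GeneSet] = []
    n_in = 0
    for gs in sets:
        n_in += 1
        if gs.category in dropped:
            continue
        measured = tuple(m for m in gs.members if m in universe_set)
        if min_size <= len(measured) <= max_size:
            out.append(GeneSet(gs.set_name, gs.category, measured))
    logger.info("retained %d of %d gene set(s)", len(out), n_in)
    return out
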