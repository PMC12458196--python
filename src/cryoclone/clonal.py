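"""Clone definition, hierarchical clone clustering, and lineage-bias statistics.

Cells are called positive for a variant when their VAF exceeds a
threshold (default 20%, strict comparison). Cells positive for at least
one selected variant are clustered on Jaccard (binary) distance between
their positive-variant sets with Ward linkage. Cell-type bias of a variant
is tested with the tie-corrected Kruskal-Wallis statistic and
Benjamini-Hochberg correction across tested variants.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .counts import Variant
from .errors import ArgumentError
from .genotyping import HeteroplasmyMatrix, VariantMetrics

log = logging.getLogger(__name__)


@dataclass
class ClonePresenceMatrix:
    cells: list[str]
    variants: list[Variant]
    presence: np.ndarray  # bool (cells x variants)
    threshold: float
    comparator: str = ">"

    @property
    def retained_cells(self) -> list[str]:
        keep = self.presence.any(axis=1)
        return [c for c, k in zip(self.cells, keep) if k]

    def positive_sets(self) -> dict[str, set[Variant]]:
        return {
            c: {v for v, p in zip(self.variants, row) if p}
            for c, row in zip(self.cells, self.presence)
        }


def binarize_presence(
    het: HeteroplasmyMatrix,
    threshold: float = 0.20,
    min_cov: int = 1,
    comparator: str = ">",
) -> ClonePresenceMatrix:
    """Per-cell variant positivity: af (default strictly) above threshold and
    coverage >= min_cov.

    ``comparator`` may be ``">"`` (VAF must exceed the threshold) or
    ``">="``; the published analyses state both and we default to strict.
    """
    ops = {">": operator.gt, ">=": operator.ge}
    if comparator not in ops:
        raise ArgumentError(f"comparator must be '>' or '>=', got {comparator!r}")
    presence = ops[comparator](het.af, threshold) & (het.cov >= min_cov)
    return ClonePresenceMatrix(
        cells=list(het.cells),
        variants=list(het.variants),
        presence=presence,
        threshold=threshold,
        comparator=comparator,
    )


def select_top_variants(
    metrics: Sequence[VariantMetrics],
    n: int = 50,
    mode: str = "mean",
) -> list[Variant]:
    """Top-n variants by pseudobulk heteroplasmy (descending), ties broken by
    position ascending."""
    if n <= 0:
        raise ArgumentError(f"n must be positive, got {n}")
    if mode == "mean":
        key = lambda m: (-m.pseudobulk_het_mean, m.variant.position)
    elif mode == "aggregate":
        key = lambda m: (-m.pseudobulk_het_aggregate, m.variant.position)
    else:
        raise ArgumentError(f"unknown pseudobulk mode {mode!r}")
    ordered = sorted(metrics, key=key)
    return [m.variant for m in ordered[:n]]


@dataclass
class CloneAssignment:
    labels: dict[str, int]
    linkage: np.ndarray | None
    k: int | None
    cut_height: float | None

    @property
    def clone_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


def jaccard_distance_matrix(presence: np.ndarray) -> np.ndarray:
    """Condensed Jaccard distances between rows of a boolean matrix.

    d(A, B) = 1 - |A & B| / |A | B|; identical non-empty sets get 0.
    """
    return pdist(presence.astype(bool), metric="jaccard")


def cluster_clones(
    presence: ClonePresenceMatrix,
    k: int | None = None,
    cut_height: float | None = None,
) -> CloneAssignment:
    """Jaccard/Ward hierarchical clustering of variant-positive cells.

    Only cells positive for >= 1 variant are clustered. Exactly one of
    ``k`` or ``cut_height`` may be supplied; when neither is, ``k``
    defaults to the number of variants with at least one positive cell.
    """
    if k is not None and cut_height is not None:
        raise ArgumentError("supply at most one of k / cut_height")
    retained = presence.retained_cells
    if not retained:
        raise ArgumentError("no cells positive for any variant")
    rows = [presence.cells.index(c) for c in retained]
    mat = presence.presence[rows]
    if len(retained) == 1:
        return CloneAssignment(labels={retained[0]: 1}, linkage=None, k=1, cut_height=None)
    if k is None and cut_height is None:
        k = int(mat.any(axis=0).sum())
        k = max(1, min(k, len(retained)))
    dist = jaccard_distance_matrix(mat)
    Z = hierarchy.linkage(dist, method="ward")
    if cut_height is not None:
        flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = {c: int(l) for c, l in zip(retained, flat)}
    return CloneAssignment(labels=labels, linkage=Z, k=k, cut_height=cut_height)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def lineage_bias(
    het: HeteroplasmyMatrix,
    groups: Mapping[str, str],
    variants: Sequence[Variant] | None = None,
    positivity_threshold: float = 0.20,
    comparator: str = ">",
) -> pd.DataFrame:
    """Kruskal-Wallis lineage-bias table with BH correction.

    Per variant, the tie-corrected H statistic over per-cell allele
    fractions (covered cells only) grouped by cell-type label, p from the
    chi-square approximation, and BH-adjusted p across all tested variants.
    Per-group mean heteroplasmy and positive-cell counts are attached.
    Variants covered in fewer than two groups are skipped (logged).
    All-identical values yield H = 0, p = 1 by convention.
    """
    if variants is None:
        variants = het.variants
    unlabeled = [c for c in het.cells if c not in groups]
    if unlabeled:
        raise ArgumentError(f"{len(unlabeled)} cells lack a group label")
    ops = {">": operator.gt, ">=": operator.ge}[comparator]
    cell_labels = np.array([groups[c] for c in het.cells])
    group_names = sorted(set(cell_labels.tolist()))
    rows = []
    for v in variants:
        j = het.variant_index(v)
        covered = het.cov[:, j] > 0
        samples = []
        means = {}
        positives = {}
        for g in group_names:
            mask = covered & (cell_labels == g)
            vals = het.af[mask, j]
            means[f"mean_het_{g}"] = float(vals.mean()) if vals.size else float("nan")
            positives[f"n_positive_{g}"] = int(np.count_nonzero(ops(vals, positivity_threshold)))
            if vals.size:
                samples.append(vals)
        if len(samples) < 2:
            log.debug("skipping %s: covered in fewer than two groups", v.label)
            continue
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append(
            {"variant": v.label, "H": float(h), "p": float(p), **means, **positives}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
        table = table.set_index("variant")
    return table


def filter_biased_variants(
    table: pd.DataFrame,
    target_group: str,
    max_p_adj: float = 0.05,
    min_cells: int = 4,
) -> list[str]:
    """Variants with BH-adjusted bias p <= max_p_adj and >= min_cells positive
    cells in the target group (inclusive comparisons)."""
    col = f"n_positive_{target_group}"
    if col not in table.columns:
        raise ArgumentError(f"unknown group {target_group!r}")
    keep = table[(table["p_adj"] <= max_p_adj) & (table[col] >= min_cells)]
    return list(keep.index)


def clone_cells_across_groups(
    presence: ClonePresenceMatrix,
    variant: Variant,
    groups: Mapping[str, str],
) -> dict[str, set[str]]:
    """Positive barcodes for one variant, partitioned by group label."""
    if variant not in presence.variants:
        import warnings

        warnings.warn(f"variant {variant.label} not in presence matrix")
        return {}
    j = presence.variants.index(variant)
    out: dict[str, set[str]] = {}
    for i, cell in enumerate(presence.cells):
        if presence.presence[i, j]:
            out.setdefault(groups[cell], set()).add(cell)
    return out
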