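"""Ambient mtDNA background estimation from empty droplets and count correction.

The workflow mirrors the empty-droplet conceptual model: barcodes are
ranked by nuclear signal, the non-cell fraction of the top droplets defines
an ambient pool, per-variant ambient allele fractions (``alpha``) are
estimated from that pool, a per-cell ambient scaling (``rho``) is fitted on
marker variants where the cell itself is presumed negative, and the
expected ambient alternate reads are subtracted from each cell's counts.

Unlike the variational original, every step here is a deterministic
closed-form estimator, which makes parameter recovery directly testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from .counts import BarcodeRecord, StrandBaseCounts, Variant
from .errors import ArgumentError, CryocloneError
from .genotyping import HeteroplasmyMatrix, compute_heteroplasmy
from .qc import rank_background_barcodes

log = logging.getLogger(__name__)


@dataclass
class AmbientProfile:
    """Per-variant ambient alternate-allele fractions from empty droplets."""

    alpha: dict[Variant, float]
    empty_droplets: set[str]
    total_ambient_reads: int
    pseudocount: float
    #: variants whose ambient fraction could not be estimated (zero coverage)
    undefined: set[Variant] = field(default_factory=set)


@dataclass
class AmbientCorrectionResult:
    rho: dict[str, float]
    corrected: StrandBaseCounts
    #: removed alternate reads per (cell, variant)
    removed: dict[tuple[str, Variant], int]
    mode: str

    @property
    def total_removed(self) -> int:
        return int(sum(self.removed.values()))


def select_empty_droplets(
    records: Sequence[BarcodeRecord],
    called_cells: set[str],
    total_droplets: int = 20_000,
    low_count_threshold: int = 1,
) -> set[str]:
    """Background droplets: top ``total_droplets`` barcodes by
    peak_region_fragments, minus called cells, keeping only barcodes with
    more than ``low_count_threshold`` mitochondrial fragments."""
    ranked = rank_background_barcodes(records, top_n=total_droplets, drop_zero_mito=False)
    by_barcode = {r.barcode: r for r in records}
    empties = {
        b
        for b in ranked
        if b not in called_cells and by_barcode[b].mito_fragments > low_count_threshold
    }
    if not empties:
        raise CryocloneError(
            "no background droplets: every candidate is a called cell or "
            f"has <= {low_count_threshold} mitochondrial fragments"
        )
    return empties


def estimate_ambient_profile(
    tensor: StrandBaseCounts,
    variants: Sequence[Variant],
    empties: set[str],
    pseudocount: float = 1.0,
) -> AmbientProfile:
    """Pooled ambient allele fraction per variant.

    ``alpha(v) = (sum alt + pseudocount * 0.5) / (sum coverage + pseudocount)``
    over all empty droplets; variants with zero empty coverage are flagged
    undefined (alpha = NaN).
    """
    if not empties:
        raise ArgumentError("empties must be non-empty")
    empty_list = sorted(empties)
    het = compute_heteroplasmy(tensor, variants, empty_list)
    alt = het.alt_total
    alpha: dict[Variant, float] = {}
    undefined: set[Variant] = set()
    for j, v in enumerate(variants):
        tot_cov = int(het.cov[:, j].sum())
        if tot_cov == 0:
            alpha[v] = float("nan")
            undefined.add(v)
            log.warning("ambient fraction undefined for %s: zero empty coverage", v.label)
        else:
            alpha[v] = (int(alt[:, j].sum()) + pseudocount * 0.5) / (tot_cov + pseudocount)
    total_reads = int(het.cov.sum())
    return AmbientProfile(
        alpha=alpha,
        empty_droplets=set(empties),
        total_ambient_reads=total_reads,
        pseudocount=pseudocount,
        undefined=undefined,
    )


def estimate_cell_ambient_fraction(
    het: HeteroplasmyMatrix,
    profile: AmbientProfile,
    marker_alpha_min: float = 0.05,
    negative_af_max: float = 0.20,
) -> dict[str, float]:
    """Per-cell ambient fraction ``rho`` from ambient-prevalent marker variants.

    Markers are variants with ``alpha >= marker_alpha_min``. For each cell,
    only markers where the cell looks negative (``af < negative_af_max``)
    contribute:

        rho(b) = sum_M alt(b, v) / sum_M cov(b, v) * alpha(v),  clipped to [0, 1].

    Cells with no usable marker coverage receive the cohort median (logged).
    """
    markers = [
        v
        for v in het.variants
        if v in profile.alpha
        and not np.isnan(profile.alpha[v])
        and profile.alpha[v] >= marker_alpha_min
    ]
    if not markers:
        raise CryocloneError(
            "no ambient marker variants with alpha >= "
            f"{marker_alpha_min}; supply multi-donor discriminating variants "
            "or an explicit marker list"
        )
    midx = np.array([het.variant_index(v) for v in markers], dtype=int)
    alphas = np.array([profile.alpha[v] for v in markers], dtype=float)
    alt = het.alt_total[:, midx]
    cov = het.cov[:, midx]
    af = het.af[:, midx]
    usable = (cov > 0) & (af < negative_af_max)
    num = np.where(usable, alt, 0).sum(axis=1).astype(float)
    den = (np.where(usable, cov, 0) * alphas).sum(axis=1)
    rho: dict[str, float] = {}
    fallback_cells = []
    values = []
    for i, cell in enumerate(het.cells):
        if den[i] > 0:
            r = float(np.clip(num[i] / den[i], 0.0, 1.0))
            rho[cell] = r
            values.append(r)
        else:
            fallback_cells.append(cell)
    median = float(np.median(values)) if values else 0.0
    if fallback_cells:
        log.info(
            "%d cells had no usable ambient marker coverage; assigned cohort median rho=%.4f",
            len(fallback_cells),
            median,
        )
    for cell in fallback_cells:
        rho[cell] = median
    return rho


def _round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def correct_counts(
    tensor: StrandBaseCounts,
    cells: Sequence[str],
    profile: AmbientProfile,
    rho: Mapping[str, float],
    mode: str = "reassign",
    rounding: str = "entry",
    negative_af_max: float = 0.20,
) -> AmbientCorrectionResult:
    """Subtract expected ambient alternate reads from each cell.

    Expected ambient alternate reads ``e(b, v) = rho(b) * cov(b, v) * alpha(v)``.

    ``rounding="entry"`` rounds each expectation half-away-from-zero
    independently; ``rounding="apportion"`` rounds the per-cell total
    removal and apportions it over that cell's variants by largest
    remainder (capped at the observed alternate count, surplus
    redistributed), which avoids the systematic under-removal that
    per-entry rounding causes when expectations are fractions of a read.
    Apportionment is done separately within the cell's presumed-negative
    entries (``af < negative_af_max``) and its allele-carrying entries, so
    the large removal capacity of homoplasmic sites cannot absorb removals
    owed to ambient-only sites.

    ``mode="reassign"`` moves removed reads to the reference allele
    (per-position coverage preserved); ``mode="drop"`` deletes them.
    """
    if mode not in ("reassign", "drop"):
        raise ArgumentError(f"unknown correction mode {mode!r}")
    if rounding not in ("entry", "apportion"):
        raise ArgumentError(f"unknown rounding {rounding!r}")
    variants = [v for v in profile.alpha if not np.isnan(profile.alpha[v])]
    variants.sort(key=lambda v: (v.position, v.alt))
    corrected = tensor.copy()
    removed: dict[tuple[str, Variant], int] = {}

    # mutate via LIL for efficient scattered writes
    lil = {key: corrected.matrix(*key).tolil() for key in
           [(b, s) for b in "ACGT" for s in ("fwd", "rev")]}

    covmat = tensor.coverage_matrix()
    for cell in cells:
        r = float(rho.get(cell, 0.0))
        if r <= 0:
            continue
        i = tensor.barcode_index(cell)
        cols = np.array([v.position - 1 for v in variants], dtype=int)
        cov = np.asarray(covmat[i, cols].todense()).ravel()
        alphas = np.array([profile.alpha[v] for v in variants])
        alt_f = np.array(
            [int(tensor.matrix(v.alt, "fwd")[i, v.position - 1]) for v in variants]
        )
        alt_r = np.array(
            [int(tensor.matrix(v.alt, "rev")[i, v.position - 1]) for v in variants]
        )
        k = alt_f + alt_r
        e = r * cov * alphas
        if rounding == "entry":
            sub = np.minimum(k, _round_half_away(e))
        else:
            with np.errstate(invalid="ignore"):
                af = np.where(cov > 0, k / np.maximum(cov, 1), 0.0)
            neg = (cov > 0) & (af < negative_af_max)
            sub = np.zeros_like(k)
            for grp in (neg, ~neg & (cov > 0)):
                if grp.any():
                    sub[grp] = _apportion(e[grp], k[grp])
        for v, s, kf, kr in zip(variants, sub, alt_f, alt_r):
            s = int(s)
            if s <= 0:
                continue
            removed[(cell, v)] = s
            # split removal across strands proportional to observed counts,
            # remainder to the strand with more reads (tie -> forward)
            tot = kf + kr
            sf = int(np.floor(s * kf / tot))
            sr = int(np.floor(s * kr / tot))
            rem = s - sf - sr
            if rem:
                if kf - sf >= kr - sr:
                    sf += rem
                else:
                    sr += rem
            sf = min(sf, int(kf))
            sr = min(sr, int(kr))
            col = v.position - 1
            if sf:
                lil[(v.alt, "fwd")][i, col] = int(kf) - sf
                if mode == "reassign":
                    lil[(v.ref, "fwd")][i, col] = int(lil[(v.ref, "fwd")][i, col]) + sf
            if sr:
                lil[(v.alt, "rev")][i, col] = int(kr) - sr
                if mode == "reassign":
                    lil[(v.ref, "rev")][i, col] = int(lil[(v.ref, "rev")][i, col]) + sr
    mats = {key: m.tocsr() for key, m in lil.items()}
    out = StrandBaseCounts(tensor.barcodes, tensor.genome_length, mats)
    return AmbientCorrectionResult(
        rho={c: float(rho.get(c, 0.0)) for c in cells},
        corrected=out,
        removed=removed,
        mode=mode,
    )


def _apportion(e: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of round(sum(e)) over entries, capped at k."""
    total = int(_round_half_away(float(e.sum())))
    if total <= 0:
        return np.zeros_like(k)
    base = np.floor(e).astype(np.int64)
    sub = np.minimum(base, k)
    remaining = total - int(sub.sum())
    if remaining > 0:
        # order by remainder descending, position order as tie-break
        remainders = e - base
        order = np.argsort(-remainders, kind="stable")
        # hand out one read at a time to entries with spare observed reads
        spare = (k - sub).astype(np.int64)
        idx = 0
        passes = 0
        while remaining > 0 and passes < 2 * len(e) + 2:
            j = order[idx % len(order)]
            if spare[j] > 0:
                sub[j] += 1
                spare[j] -= 1
                remaining -= 1
            idx += 1
            if idx % len(order) == 0:
                passes += 1
                if spare.sum() == 0:
                    break
    return sub


@dataclass
class BackgroundReport:
    """Summary emitted by :func:`remove_background`."""

    n_empty_droplets: int
    n_cells: int
    n_variants: int
    total_ambient_reads: int
    total_removed: int
    rho_median: float
    rho_mean: float
    alpha: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_empty_droplets": self.n_empty_droplets,
            "n_cells": self.n_cells,
            "n_variants": self.n_variants,
            "total_ambient_reads": self.total_ambient_reads,
            "total_removed": self.total_removed,
            "rho_median": self.rho_median,
            "rho_mean": self.rho_mean,
            "alpha": self.alpha,
        }


def remove_background(
    tensor: StrandBaseCounts,
    records: Sequence[BarcodeRecord],
    called_cells: Sequence[str],
    variants: Sequence[Variant] | None = None,
    reference: str | None = None,
    total_droplets: int = 20_000,
    low_count_threshold: int = 1,
    pseudocount: float = 1.0,
    marker_alpha_min: float = 0.05,
    negative_af_max: float = 0.20,
    mode: str = "reassign",
    rounding: str = "apportion",
) -> tuple[AmbientCorrectionResult, BackgroundReport]:
    """End-to-end background removal on in-memory objects.

    Either an explicit variant list or a reference sequence (from which
    candidate variants are enumerated over the called cells) must be given.
    Returns the correction result plus a report; orchestration order is
    rank -> select empties -> ambient profile -> per-cell rho -> correction.
    """
    from .genotyping import call_candidate_variants

    called = list(called_cells)
    if variants is None:
        if reference is None:
            raise ArgumentError("supply either a variant list or a reference sequence")
        variants = call_candidate_variants(tensor, reference, called)
    variants = list(variants)
    if not variants:
        raise CryocloneError("no variants to correct")

    empties = select_empty_droplets(
        records, set(called), total_droplets=total_droplets,
        low_count_threshold=low_count_threshold,
    )
    empties &= set(tensor.barcodes)
    if not empties:
        raise CryocloneError("no selected empty droplet present in the count tensor")
    profile = estimate_ambient_profile(tensor, variants, empties, pseudocount=pseudocount)
    het = compute_heteroplasmy(tensor, variants, called)
    rho = estimate_cell_ambient_fraction(
        het, profile, marker_alpha_min=marker_alpha_min, negative_af_max=negative_af_max
    )
    result = correct_counts(tensor, called, profile, rho, mode=mode, rounding=rounding)
    rho_vals = np.array([result.rho[c] for c in called]) if called else np.array([0.0])
    report = BackgroundReport(
        n_empty_droplets=len(empties),
        n_cells=len(called),
        n_variants=len(variants),
        total_ambient_reads=profile.total_ambient_reads,
        total_removed=result.total_removed,
        rho_median=float(np.median(rho_vals)),
        rho_mean=float(np.mean(rho_vals)),
        alpha={v.label: profile.alpha[v] for v in variants},
    )
    return result, report
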