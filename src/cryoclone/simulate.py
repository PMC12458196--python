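"""Synthetic droplet-experiment generator.

Produces a :class:`~cryoclone.counts.StrandBaseCounts` tensor, per-barcode
QC records, and full ground truth for a multi-donor mixing experiment:
donor-distinct homoplasmic germline haplotypes, within-donor clones
carrying somatic heteroplasmic variants, a shared ambient pool
contaminating every droplet, empty droplets drawn purely from that pool,
strand-split sequencing counts with substitution errors, and QC
covariates with a configurable failure fraction.

Generative model
----------------
1. Every cell gets its donor's germline variants at heteroplasmy 1 plus
   its clone's somatic variants at their configured heteroplasmy.
2. The ambient pool allele fraction per variant is the expected-coverage-
   weighted mean of all cells' true allele fractions.
3. Per cell and position, coverage ~ NegativeBinomial(mean, dispersion);
   alternate reads ~ Binomial(coverage, (1 - rho) * own_af + rho * ambient_af);
   a symmetric per-read substitution error then moves reads uniformly to
   the other three bases; each base count is split across strands with
   Binomial(strand_split).
4. Empty droplets sample the ambient pool at low depth.

Everything is reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from .counts import (
    BASES,
    BarcodeRecord,
    StrandBaseCounts,
    Variant,
    write_barcode_summary,
    write_strand_counts,
)
from .errors import ArgumentError

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class CloneSpec:
    """One clone: cell count, somatic (variant, heteroplasmy) pairs, and a
    cell-type label distribution."""

    n_cells: int
    somatic: tuple[tuple[Variant, float], ...] = ()
    cell_type_weights: tuple[tuple[str, float], ...] = (("typeA", 1.0),)


@dataclass(frozen=True)
class DonorSpec:
    donor_id: str
    germline: tuple[Variant, ...]
    clones: tuple[CloneSpec, ...]


@dataclass
class SimulationConfig:
    seed: int
    genome_length: int = 2000
    donors: tuple[DonorSpec, ...] = ()
    shared_germline: tuple[Variant, ...] = ()
    depth_mean: float | Mapping[str, float] = 20.0
    depth_dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    strand_split: float = 0.5
    seq_error_rate: float = 5e-4
    ambient_rho: float | tuple[float, float] = 0.05  # constant, or Beta(a, b)
    n_empty: int = 5000
    empty_depth_mean: float = 2.0
    empty_depth_dispersion: float = 2.0
    doublet_rate: float = 0.0
    qc_fail_fraction: float = 0.0
    artifact_variants: tuple[tuple[Variant, float], ...] = ()
    reference: str | None = None

    def validate(self) -> None:
        if self.genome_length < 1:
            raise ArgumentError("genome_length must be positive")
        for frac_name in ("strand_split", "seq_error_rate", "doublet_rate", "qc_fail_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ArgumentError(f"{frac_name} must be in [0, 1], got {v}")
        if isinstance(self.ambient_rho, tuple):
            a, b = self.ambient_rho
            if a <= 0 or b <= 0:
                raise ArgumentError("Beta parameters for ambient_rho must be positive")
        elif not 0.0 <= self.ambient_rho <= 1.0:
            raise ArgumentError("ambient_rho must be in [0, 1]")
        positions: set[int] = set()
        for v, _het in self.all_variants_with_origin():
            if not 1 <= v.position <= self.genome_length:
                raise ArgumentError(f"variant {v.label} outside [1, {self.genome_length}]")
            if v.position in positions:
                raise ArgumentError(f"overlapping variant positions at {v.position}")
            positions.add(v.position)
        for donor in self.donors:
            for clone in donor.clones:
                for _v, het in clone.somatic:
                    if not 0.0 < het < 1.0:
                        raise ArgumentError(f"somatic heteroplasmy must be in (0, 1), got {het}")
        if self.reference is not None and len(self.reference) != self.genome_length:
            raise ArgumentError("reference length does not match genome_length")

    def all_variants_with_origin(self):
        for v in self.shared_germline:
            yield v, None
        for donor in self.donors:
            for v in donor.germline:
                yield v, None
            for clone in donor.clones:
                for v, het in clone.somatic:
                    yield v, het
        for v, het in self.artifact_variants:
            yield v, het

    def all_variants(self) -> list[Variant]:
        seen = [v for v, _ in self.all_variants_with_origin()]
        return sorted(seen, key=lambda v: v.position)


@dataclass
class BarcodeTruth:
    barcode: str
    is_cell: bool
    donor: str | None = None
    clone: str | None = None
    cell_type: str | None = None
    rho: float = 0.0
    is_doublet: bool = False
    qc_fail: bool = False


@dataclass
class SimulationTruth:
    barcodes: dict[str, BarcodeTruth]
    ambient_alpha: dict[Variant, float]
    #: variant -> ("shared"|"germline"|"somatic"|"artifact", donor_id|None, clone|None, het)
    variant_origin: dict[Variant, tuple[str, str | None, str | None, float]]
    reference: str
    config: SimulationConfig
    #: true per-variant heteroplasmy per cell barcode
    cell_af: dict[str, dict[Variant, float]] = field(default_factory=dict)

    def cells(self) -> list[str]:
        return [b for b, t in self.barcodes.items() if t.is_cell]

    def singlets(self) -> list[str]:
        return [b for b, t in self.barcodes.items() if t.is_cell and not t.is_doublet]

    def doublets(self) -> list[str]:
        return [b for b, t in self.barcodes.items() if t.is_doublet]

    def empty_barcodes(self) -> list[str]:
        return [b for b, t in self.barcodes.items() if not t.is_cell]

    def donor_discriminating_variants(self) -> list[Variant]:
        return sorted(
            (v for v, (kind, _d, _c, _h) in self.variant_origin.items() if kind == "germline"),
            key=lambda v: v.position,
        )

    def donor_of(self, variant: Variant) -> str | None:
        return self.variant_origin[variant][1]


# -- random configuration builders -------------------------------------------


def _random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _draw_variants(
    rng: np.random.Generator,
    reference: str,
    n: int,
    used: set[int],
) -> list[Variant]:
    length = len(reference)
    free = np.array(sorted(set(range(1, length + 1)) - used), dtype=int)
    if len(free) < n:
        raise ArgumentError("genome too short for the requested number of variants")
    pos = rng.choice(free, size=n, replace=False)
    out = []
    for p in sorted(int(x) for x in pos):
        ref = reference[p - 1]
        alts = [b for b in BASES if b != ref]
        alt = alts[int(rng.integers(0, 3))]
        out.append(Variant(p, ref, alt))
        used.add(p)
    return out


def two_donor_mixing_config(
    seed: int,
    n_cells_per_donor: int = 1000,
    n_discriminating_per_donor: int = 20,
    n_shared_germline: int = 10,
    clone_heteroplasmies: Sequence[float] = (0.3, 0.6, 0.9),
    ambient_rho: float | tuple[float, float] = 0.05,
    n_empty: int = 5000,
    depth_mean: float = 20.0,
    genome_length: int = 2000,
    doublet_rate: float = 0.0,
    seq_error_rate: float = 5e-4,
    qc_fail_fraction: float = 0.0,
    cell_types: Sequence[str] = ("typeA", "typeB", "typeC", "typeD"),
) -> SimulationConfig:
    """Two-donor mixing preset: distinct homoplasmic haplotypes per donor,
    shared germline variants, three clones per donor, an ambient pool, and
    empty droplets."""
    rng = np.random.default_rng(seed)
    reference = _random_reference(rng, genome_length)
    used: set[int] = set()
    shared = tuple(_draw_variants(rng, reference, n_shared_germline, used))
    donors = []
    for d in range(2):
        germline = tuple(_draw_variants(rng, reference, n_discriminating_per_donor, used))
        clones = []
        sizes = _split_sizes(n_cells_per_donor, len(clone_heteroplasmies))
        for ci, (het, size) in enumerate(zip(clone_heteroplasmies, sizes)):
            somatic = tuple((v, het) for v in _draw_variants(rng, reference, 1, used))
            weights = tuple((t, 1.0 / len(cell_types)) for t in cell_types)
            clones.append(CloneSpec(n_cells=size, somatic=somatic, cell_type_weights=weights))
        donors.append(DonorSpec(donor_id=f"donor{d + 1}", germline=germline, clones=tuple(clones)))
    return SimulationConfig(
        seed=seed,
        genome_length=genome_length,
        donors=tuple(donors),
        shared_germline=shared,
        depth_mean=depth_mean,
        ambient_rho=ambient_rho,
        n_empty=n_empty,
        doublet_rate=doublet_rate,
        seq_error_rate=seq_error_rate,
        qc_fail_fraction=qc_fail_fraction,
        reference=reference,
    )


def _split_sizes(total: int, parts: int) -> list[int]:
    base = total // parts
    sizes = [base] * parts
    for i in range(total - base * parts):
        sizes[i] += 1
    return sizes


def clonal_config(
    seed: int,
    n_clones: int = 5,
    cells_per_clone: int = 40,
    heteroplasmy: float = 0.6,
    depth_mean: float = 20.0,
    genome_length: int = 1000,
    seq_error_rate: float = 0.0,
) -> SimulationConfig:
    """Single-donor preset: ``n_clones`` clones with one marker variant each."""
    rng = np.random.default_rng(seed)
    reference = _random_reference(rng, genome_length)
    used: set[int] = set()
    clones = []
    for c in range(n_clones):
        somatic = tuple((v, heteroplasmy) for v in _draw_variants(rng, reference, 1, used))
        clones.append(CloneSpec(n_cells=cells_per_clone, somatic=somatic))
    donor = DonorSpec(donor_id="donor1", germline=(), clones=tuple(clones))
    return SimulationConfig(
        seed=seed,
        genome_length=genome_length,
        donors=(donor,),
        depth_mean=depth_mean,
        ambient_rho=0.0,
        n_empty=0,
        seq_error_rate=seq_error_rate,
        reference=reference,
    )


# -- core generator -----------------------------------------------------------


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[StrandBaseCounts, list[BarcodeRecord], SimulationTruth]:
    """Run the generative model; see the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    reference = config.reference or _random_reference(rng, L)
    ref_idx = np.array([_BASE_INDEX[b] for b in reference], dtype=np.int8)

    variants = config.all_variants()
    vpos = np.array([v.position - 1 for v in variants], dtype=int)
    valt = np.array([_BASE_INDEX[v.alt] for v in variants], dtype=np.int8)

    variant_origin: dict[Variant, tuple[str, str | None, str | None, float]] = {}
    for v in config.shared_germline:
        variant_origin[v] = ("shared", None, None, 1.0)
    for donor in config.donors:
        for v in donor.germline:
            variant_origin[v] = ("germline", donor.donor_id, None, 1.0)
        for ci, clone in enumerate(donor.clones):
            for v, het in clone.somatic:
                variant_origin[v] = ("somatic", donor.donor_id, f"{donor.donor_id}.c{ci + 1}", het)
    for v, het in config.artifact_variants:
        variant_origin[v] = ("artifact", None, None, het)

    # -- cell roster and true per-cell allele fractions
    cell_rows: list[BarcodeTruth] = []
    af_rows: list[np.ndarray] = []
    depth_means: list[float] = []
    vindex = {v: j for j, v in enumerate(variants)}
    counter = 0
    for donor in config.donors:
        for ci, clone in enumerate(donor.clones):
            types, weights = zip(*clone.cell_type_weights)
            w = np.array(weights, dtype=float)
            w /= w.sum()
            drawn_types = rng.choice(len(types), size=clone.n_cells, p=w)
            for t_idx in drawn_types:
                counter += 1
                barcode = f"CELL{counter:06d}"
                ctype = types[int(t_idx)]
                af = np.zeros(len(variants))
                for v in config.shared_germline:
                    af[vindex[v]] = 1.0
                for v in donor.germline:
                    af[vindex[v]] = 1.0
                for v, het in clone.somatic:
                    af[vindex[v]] = het
                for v, het in config.artifact_variants:
                    af[vindex[v]] = het
                cell_rows.append(
                    BarcodeTruth(
                        barcode=barcode,
                        is_cell=True,
                        donor=donor.donor_id,
                        clone=f"{donor.donor_id}.c{ci + 1}",
                        cell_type=ctype,
                    )
                )
                af_rows.append(af)
                depth_means.append(_depth_mean_for(config, ctype))

    # -- constructed doublets: pairs of cells, preferentially cross-donor
    n_doublets = int(round(config.doublet_rate * len(cell_rows)))
    if n_doublets and len(config.donors) >= 2:
        by_donor = {
            d.donor_id: [i for i, t in enumerate(cell_rows) if t.donor == d.donor_id]
            for d in config.donors
        }
        donor_ids = list(by_donor)
        for k in range(n_doublets):
            d1, d2 = donor_ids[0], donor_ids[1]
            i = int(rng.choice(by_donor[d1]))
            j = int(rng.choice(by_donor[d2]))
            counter += 1
            barcode = f"DBLT{counter:06d}"
            cell_rows.append(
                BarcodeTruth(
                    barcode=barcode,
                    is_cell=True,
                    donor=None,
                    clone=None,
                    cell_type=cell_rows[i].cell_type,
                    is_doublet=True,
                )
            )
            af_rows.append((af_rows[i] + af_rows[j]) / 2.0)
            depth_means.append(depth_means[i] + depth_means[j])

    n_cells = len(cell_rows)
    af_true = np.array(af_rows) if af_rows else np.zeros((0, len(variants)))
    depth_mean_arr = np.array(depth_means)

    # -- ambient pool: expected-coverage-weighted mean of true allele fractions
    if n_cells and depth_mean_arr.sum() > 0:
        alpha = (af_true * depth_mean_arr[:, None]).sum(axis=0) / depth_mean_arr.sum()
    else:
        alpha = np.zeros(len(variants))
    ambient_alpha = {v: float(alpha[j]) for j, v in enumerate(variants)}

    # -- per-cell ambient fraction rho
    if isinstance(config.ambient_rho, tuple):
        a, b = config.ambient_rho
        rho = rng.beta(a, b, size=n_cells)
    else:
        rho = np.full(n_cells, float(config.ambient_rho))
    for t, r in zip(cell_rows, rho):
        t.rho = float(r)

    mix_af = (1.0 - rho[:, None]) * af_true + rho[:, None] * alpha[None, :]

    builder = _TensorBuilder(L, ref_idx, vpos, valt, config.strand_split, config.seq_error_rate, rng)
    cell_totals = builder.add_block(depth_mean_arr, config.depth_dispersion, mix_af)

    # -- empty droplets, purely ambient
    empty_rows: list[BarcodeTruth] = []
    if config.n_empty:
        empty_mean = np.full(config.n_empty, float(config.empty_depth_mean))
        empty_af = np.tile(alpha, (config.n_empty, 1))
        empty_totals = builder.add_block(empty_mean, config.empty_depth_dispersion, empty_af)
        for k in range(config.n_empty):
            counter += 1
            empty_rows.append(BarcodeTruth(barcode=f"EMPT{counter:06d}", is_cell=False))
    else:
        empty_totals = np.zeros(0, dtype=np.int64)

    all_rows = cell_rows + empty_rows
    barcodes = [t.barcode for t in all_rows]
    tensor = builder.build(barcodes)

    # -- QC covariates
    records = _qc_records(rng, config, cell_rows, empty_rows, cell_totals, empty_totals)

    truth = SimulationTruth(
        barcodes={t.barcode: t for t in all_rows},
        ambient_alpha=ambient_alpha,
        variant_origin=variant_origin,
        reference=reference,
        config=config,
        cell_af={
            t.barcode: {v: float(af_true[i, j]) for v, j in vindex.items()}
            for i, t in enumerate(cell_rows)
        },
    )
    return tensor, records, truth


def _depth_mean_for(config: SimulationConfig, cell_type: str) -> float:
    if isinstance(config.depth_mean, Mapping):
        try:
            return float(config.depth_mean[cell_type])
        except KeyError:
            raise ArgumentError(f"no depth mean configured for cell type {cell_type!r}") from None
    return float(config.depth_mean)


class _TensorBuilder:
    """Accumulates strand-split per-base count matrices block by block."""

    CHUNK = 1000

    def __init__(self, L, ref_idx, vpos, valt, strand_split, error_rate, rng):
        self.L = L
        self.ref_idx = ref_idx
        self.vpos = vpos
        self.valt = valt
        self.strand_split = strand_split
        self.error_rate = error_rate
        self.rng = rng
        self.chunks: dict[tuple[str, str], list[sparse.csr_matrix]] = {
            (b, s): [] for b in BASES for s in ("fwd", "rev")
        }
        # the 3 non-reference bases per column, for error routing
        others = np.empty((L, 3), dtype=np.int8)
        for b in range(4):
            cols = np.nonzero(ref_idx == b)[0]
            others[cols] = [x for x in range(4) if x != b]
        self.others = others

    def add_block(self, depth_means: np.ndarray, dispersion: float, af: np.ndarray) -> np.ndarray:
        """Simulate a block of droplets; returns total reads per droplet."""
        totals = np.zeros(len(depth_means), dtype=np.int64)
        for start in range(0, len(depth_means), self.CHUNK):
            stop = min(start + self.CHUNK, len(depth_means))
            totals[start:stop] = self._chunk(depth_means[start:stop], dispersion, af[start:stop])
        return totals

    def _chunk(self, means: np.ndarray, dispersion: float, af: np.ndarray) -> np.ndarray:
        rng = self.rng
        n = len(means)
        L = self.L
        size = float(dispersion)
        p = size / (size + means)
        cov = rng.negative_binomial(size, p[:, None], size=(n, L)).astype(np.int64)

        base_counts = [np.zeros((n, L), dtype=np.int64) for _ in range(4)]

        # true alternate reads at variant columns
        alt_true = np.zeros((n, L), dtype=np.int64)
        if len(self.vpos):
            vcov = cov[:, self.vpos]
            alt_true[:, self.vpos] = rng.binomial(vcov, np.clip(af, 0.0, 1.0))
        ref_true = cov - alt_true

        e = self.error_rate
        if e > 0:
            flips_ref = rng.binomial(ref_true, e)
            ref_true = ref_true - flips_ref
            flips_alt = np.zeros_like(alt_true)
            if len(self.vpos):
                flips_alt[:, self.vpos] = rng.binomial(alt_true[:, self.vpos], e)
            alt_true = alt_true - flips_alt
        else:
            flips_ref = flips_alt = None

        # scatter reference reads to the reference base of each column
        for b in range(4):
            cols = self.ref_idx == b
            base_counts[b][:, cols] += ref_true[:, cols]
        # scatter alternate reads
        for b in range(4):
            sel = self.valt == b
            if sel.any():
                cols = self.vpos[sel]
                base_counts[b][:, cols] += alt_true[:, cols]

        if e > 0:
            self._route_errors(base_counts, flips_ref, source="ref")
            self._route_errors(base_counts, flips_alt, source="alt")

        # strand split and sparsify
        for b, name in enumerate(BASES):
            counts = base_counts[b]
            fwd = rng.binomial(counts, self.strand_split)
            rev = counts - fwd
            self.chunks[(name, "fwd")].append(sparse.csr_matrix(fwd))
            self.chunks[(name, "rev")].append(sparse.csr_matrix(rev))
        return cov.sum(axis=1)

    def _route_errors(self, base_counts, flips: np.ndarray, source: str) -> None:
        """Distribute flipped reads uniformly over the three non-source bases."""
        rng = self.rng
        rows, cols = np.nonzero(flips)
        if not len(rows):
            return
        f = flips[rows, cols]
        b1 = rng.binomial(f, 1.0 / 3.0)
        rem = f - b1
        b2 = rng.binomial(rem, 0.5)
        b3 = rem - b2
        if source == "ref":
            targets = self.others[cols]  # (k, 3) base indices != ref
        else:
            # non-alt bases per flipped variant column, in base order
            alt_at = np.zeros(self.L, dtype=np.int8)
            alt_at[self.vpos] = self.valt
            targets = np.empty((len(cols), 3), dtype=np.int8)
            for i, c in enumerate(cols):
                a = alt_at[c]
                targets[i] = [x for x in range(4) if x != a]
        for slot, amount in enumerate((b1, b2, b3)):
            for b in range(4):
                sel = targets[:, slot] == b
                if sel.any():
                    np.add.at(base_counts[b], (rows[sel], cols[sel]), amount[sel])

    def build(self, barcodes: Sequence[str]) -> StrandBaseCounts:
        mats = {}
        for key, chunks in self.chunks.items():
            if chunks:
                mats[key] = sparse.vstack(chunks, format="csr")
            else:
                mats[key] = sparse.csr_matrix((len(barcodes), self.L), dtype=np.int64)
        return StrandBaseCounts(list(barcodes), self.L, mats)


def _qc_records(
    rng: np.random.Generator,
    config: SimulationConfig,
    cell_rows: list[BarcodeTruth],
    empty_rows: list[BarcodeTruth],
    cell_totals: np.ndarray,
    empty_totals: np.ndarray,
) -> list[BarcodeRecord]:
    records: list[BarcodeRecord] = []
    n_cells = len(cell_rows)
    fail = np.zeros(n_cells, dtype=bool)
    if n_cells and config.qc_fail_fraction > 0:
        n_fail = int(round(config.qc_fail_fraction * n_cells))
        fail[rng.choice(n_cells, size=n_fail, replace=False)] = True
    peak_frags = rng.negative_binomial(5, 5 / (5 + 10_000.0), size=n_cells) + 500
    tss = np.clip(rng.normal(4.0, 0.8, size=n_cells), 1.6, None)
    nuc = np.abs(rng.normal(1.0, 0.3, size=n_cells))
    npeaks = rng.negative_binomial(5, 5 / (5 + 5000.0), size=n_cells) + 300
    frip = np.clip(rng.beta(8, 2, size=n_cells), 0.0, 1.0)
    for i, t in enumerate(cell_rows):
        t.qc_fail = bool(fail[i])
        records.append(
            BarcodeRecord(
                barcode=t.barcode,
                mito_fragments=max(1, int(cell_totals[i] // 2)),
                peak_region_fragments=int(peak_frags[i]),
                # failed cells get a TSS below every published lower bound
                tss_enrichment=0.5 if fail[i] else float(tss[i]),
                nucleosome_signal=float(nuc[i]),
                n_count_peaks=int(npeaks[i]),
                frip=float(frip[i]),
                is_cell=True,
            )
        )
    empty_peaks = rng.integers(10, 200, size=len(empty_rows))
    for k, t in enumerate(empty_rows):
        records.append(
            BarcodeRecord(
                barcode=t.barcode,
                mito_fragments=max(0, int(empty_totals[k] // 2)),
                peak_region_fragments=int(empty_peaks[k]),
                tss_enrichment=0.3,
                nucleosome_signal=1.0,
                n_count_peaks=int(empty_peaks[k]),
                frip=0.05,
                is_cell=False,
            )
        )
    return records


def simulate_mixing(
    preset: str = "two_donor_svz",
    seed: int = 0,
    **overrides,
) -> tuple[StrandBaseCounts, list[BarcodeRecord], SimulationTruth]:
    """Convenience preset runner.

    ``two_donor_svz``: 2 donors x 1,000 cells, 20 discriminating germline
    variants per donor, 10 shared, 3 clones per donor at heteroplasmy
    0.3/0.6/0.9, ambient fraction 0.05, 5,000 empty droplets, mean depth 20.
    The genome length is scaled down to 2,000 positions to keep desk-scale
    runtimes; per-position depth (and hence all allele-fraction statistics)
    is unaffected.
    """
    if preset != "two_donor_svz":
        raise ArgumentError(f"unknown preset {preset!r}")
    config = two_donor_mixing_config(seed, **overrides)
    return simulate_experiment(config)


def write_simulation(
    tensor: StrandBaseCounts,
    records: Sequence[BarcodeRecord],
    truth: SimulationTruth,
    out_dir: str | Path,
) -> None:
    """Write the simulated experiment as plain-text tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_strand_counts(tensor, out_dir / "counts")
    write_barcode_summary(records, out_dir / "singlecell.csv")
    (out_dir / "reference.txt").write_text(truth.reference + "\n")
    with (out_dir / "truth_barcodes.tsv").open("w") as fh:
        fh.write("barcode\tis_cell\tdonor\tclone\tcell_type\trho\tis_doublet\tqc_fail\n")
        for t in truth.barcodes.values():
            fh.write(
                f"{t.barcode}\t{int(t.is_cell)}\t{t.donor or ''}\t{t.clone or ''}\t"
                f"{t.cell_type or ''}\t{t.rho:.6g}\t{int(t.is_doublet)}\t{int(t.qc_fail)}\n"
            )
    with (out_dir / "truth_variants.tsv").open("w") as fh:
        fh.write("variant\tkind\tdonor\tclone\theteroplasmy\tambient_alpha\n")
        for v, (kind, donor, clone, het) in sorted(
            truth.variant_origin.items(), key=lambda kv: kv[0].position
        ):
            fh.write(
                f"{v.label}\t{kind}\t{donor or ''}\t{clone or ''}\t{het:.6g}\t"
                f"{truth.ambient_alpha[v]:.6g}\n"
            )
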