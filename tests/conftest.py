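import numpy as np
import pytest

from cryoclone.counts import BASES, StrandBaseCounts, Variant


def random_tensor(rng: np.random.Generator, n_barcodes: int = 8, genome_length: int = 40,
                  density: float = 0.3, max_count: int = 30) -> StrandBaseCounts:
    """Random sparse strand-count tensor for round-trip/property tests."""
    barcodes = [f"BC{i:03d}" for i in range(n_barcodes)]
    entries = []
    for b in barcodes:
        for pos in range(1, genome_length + 1):
            if rng.random() > density:
                continue
            for base in BASES:
                for strand in ("fwd", "rev"):
                    if rng.random() < 0.5:
                        entries.append((b, pos, base, strand, int(rng.integers(0, max_count))))
    return StrandBaseCounts.from_entries(barcodes, genome_length, entries)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_tensor():
    """2 barcodes, 10 positions, hand-built counts at position 5 (ref G, alt A)."""
    entries = [
        ("cellA", 5, "G", "fwd", 8),
        ("cellA", 5, "G", "rev", 7),
        ("cellA", 5, "A", "fwd", 3),
        ("cellA", 5, "A", "rev", 2),
        ("cellB", 5, "G", "fwd", 10),
        ("cellB", 5, "G", "rev", 10),
        ("cellB", 2, "C", "fwd", 4),
    ]
    return StrandBaseCounts.from_entries(["cellA", "cellB"], 10, entries)


@pytest.fixture
def v5():
    return Variant(5, "G", "A")
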