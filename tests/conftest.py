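import numpy as np
import pandas as pd
import pytest

from cpphylo.alignment import Alignment, SampleMetadata
from cpphylo.haplotypes import HaplotypeTable


@pytest.fixture
def small_alignment() -> Alignment:
    """6 samples, 8 bp, two populations, 3 distinct haplotypes."""
    seqs = {
        "a1": "ACGTACGT",
        "a2": "ACGTACGT",
        "a3": "ACGAACGT",
        "b1": "ACGAACGT",
        "b2": "ACGAACTT",
        "b3": "ACGAACTT",
    }
    return Alignment(list(seqs), list(seqs.values()))


@pytest.fixture
def small_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("a1", "A", "north", 21.0, -99.0),
        SampleMetadata("a2", "A", "north", 21.0, -99.0),
        SampleMetadata("a3", "A", "north", 21.0, -99.0),
        SampleMetadata("b1", "B", "central", 19.5, -97.0),
        SampleMetadata("b2", "B", "central", 19.5, -97.0),
        SampleMetadata("b3", "B", "central", 19.5, -97.0),
    ]


def make_table(seqs: list[str], pops: list[str] | None = None) -> HaplotypeTable:
    """Haplotype table with one sample per sequence (test helper)."""
    labels = [f"H{i + 1:02d}" for i in range(len(seqs))]
    pops = pops or ["P"] * len(seqs)
    counts = pd.DataFrame(0, index=labels, columns=list(dict.fromkeys(pops)), dtype=int)
    for lab, pop in zip(labels, pops):
        counts.loc[lab, pop] += 1
    return HaplotypeTable(list(seqs), labels, counts, {})


@pytest.fixture(scope="session")
def tiny_reference_table() -> pd.DataFrame:
    """Small ABC reference table shared across tests (300 sims/scenario)."""
    from cpphylo.abc_inference import build_reference_table

    return build_reference_table(300, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    """Fresh seeded generator per test, so outcomes are order-independent."""
    return np.random.default_rng(20260919)
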