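"""Shared fixtures: a ten-codon toy reference and read builders."""

from __future__ import annotations

import numpy as np
import pytest

from mistransevo.amplicon_io import AlignedRead, PopulationAlignment, Reference

# ATG AAA CCC GGG TTT GCT GAA ATG TGG TAA
TOY_CDS = "ATGAAACCCGGGTTTGCTGAAATGTGGTAA"


@pytest.fixture
def toy_reference() -> Reference:
    return Reference("toy", TOY_CDS)


def make_read(
    seq: str,
    quality: int | list[int] | np.ndarray = 30,
    read_id: str = "r",
    barcode: str | None = None,
) -> AlignedRead:
    if np.isscalar(quality):
        quals = np.full(len(seq), int(quality), dtype=np.int16)
    else:
        quals = np.asarray(quality, dtype=np.int16)
    quals = np.where(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("-"), -1, quals)
    return AlignedRead(read_id, seq, quals, barcode)


def make_population(seqs: list[str], quality: int = 30, **labels) -> PopulationAlignment:
    reads = [make_read(s, quality, read_id=f"r{i}") for i, s in enumerate(seqs)]
    return PopulationAlignment(reads, **labels)


@pytest.fixture
def mutate():
    """Return a copy of a sequence with one base substituted (1-based pos)."""

    def _mutate(seq: str, pos: int, base: str) -> str:
        return seq[: pos - 1] + base + seq[pos:]

    return _mutate
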