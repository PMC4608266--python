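from __future__ import annotations

import numpy as np
import pytest

from lincmir.duplex import AlignmentColumn, DuplexAlignment, PairState
from lincmir.seq_io import MatureMiRNA, Transcript


def make_alignment(
    length: int = 21,
    defects: list[tuple[int, str]] | None = None,
    site_end: int = 200,
    mirna_id: str = "miR-test",
    transcript_id: str = "tx-test",
) -> DuplexAlignment:
    """Synthetic alignment with the given defect placements.

    ``defects`` entries are (miRNA position, kind) with kind MISMATCH /
    BULGE_MIRNA / BULGE_TARGET; a BULGE_TARGET at position p inserts an
    unpaired transcript base between miRNA positions p and p+1 (so p < L).
    Coordinates are synthesized downward from ``site_end``.
    """
    defects = defects or []
    kind_at = {}
    bulge_after = set()
    for pos, kind in defects:
        if kind == "BULGE_TARGET":
            bulge_after.add(pos)
        else:
            kind_at[pos] = kind
    columns = []
    coord = site_end
    for pos in range(1, length + 1):
        kind = kind_at.get(pos)
        if kind == "BULGE_MIRNA":
            columns.append(AlignmentColumn(pos, None, PairState.BULGE_MIRNA))
        elif kind == "MISMATCH":
            columns.append(AlignmentColumn(pos, coord, PairState.MISMATCH))
            coord -= 1
        else:
            columns.append(AlignmentColumn(pos, coord, PairState.WC))
            coord -= 1
        if pos in bulge_after:
            columns.append(AlignmentColumn(None, coord, PairState.BULGE_TARGET))
            coord -= 1
    tpos = [c.transcript_pos for c in columns if c.transcript_pos is not None]
    return DuplexAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=min(tpos),
        site_end=max(tpos),
        columns=tuple(columns),
        mfe_site=-20.0,
        mfe_perfect=-40.0,
        mfe_ratio=0.5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def mirna21():
    # GC-balanced 21-mer used across alignment tests
    return MatureMiRNA("miR-fix21", "UGACGAAGCUCAAGUCGGAUC")


@pytest.fixture
def make_transcript():
    def _make(seq: str, tid: str = "tx1", biotype: str = "lincRNA"):
        return Transcript(tid, seq, biotype)

    return _make
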