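"""Target / decoy rule engine over duplex alignments.

Cleavage-target rule: at most one mismatch or indel at miRNA positions 9-12,
at most 4 defect nucleotides elsewhere, and no run of two or more consecutive
mismatches anywhere.  Decoy (target-mimic) rule: 2-5 mismatches/indels at
positions 9-12, perfect (WC or G:U) pairing at positions 2-8 with no adjacent
indel, and at most 4 defects in the remaining regions (position 1 and 13..L).
G:U wobbles count as pairs unless demoted via the scan flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .duplex import DuplexAlignment, PairState

CENTRAL_REGION = range(9, 13)  # miRNA positions 9-12, inclusive
SEED_REGION = range(2, 9)      # miRNA positions 2-8, inclusive


class Verdict(Enum):
    TARGET = "target"
    DECOY = "decoy"
    NONE = "none"


@dataclass(frozen=True)
class RegionDiagnostics:
    """Per-region defect counts for one alignment.

    Defect assignment: a mismatch or unpaired miRNA base at miRNA position i
    belongs to the region containing i; an unpaired transcript base between
    miRNA positions i and i+1 belongs to the region containing i (the 5'-ward
    flank).
    """

    defects_9_12: int
    perfect_2_8: bool
    defects_other_target: int  # defects outside 9-12 (positions 1-8, 13..L)
    defects_other_decoy: int   # defects at position 1 and 13..L only
    max_mismatch_run: int

    def __post_init__(self) -> None:
        if min(self.defects_9_12, self.defects_other_target,
               self.defects_other_decoy, self.max_mismatch_run) < 0:
            raise ValueError("diagnostic counts must be >= 0")


@dataclass(frozen=True)
class InteractionCall:
    verdict: Verdict
    diagnostics: RegionDiagnostics
    alignment: DuplexAlignment


def _assigned_position(columns: Sequence, index: int) -> int:
    """miRNA position a defect column is charged to (5'-ward flank for bulges)."""
    col = columns[index]
    if col.mirna_pos is not None:
        return col.mirna_pos
    # BULGE_TARGET: columns are ordered by miRNA position 1..L, so the
    # 5'-ward flanking miRNA position is the nearest one at a lower index
    for k in range(index - 1, -1, -1):
        if columns[k].mirna_pos is not None:
            return columns[k].mirna_pos
    return 1


def region_diagnostics(alignment: DuplexAlignment) -> RegionDiagnostics:
    """Count defects per rule region for one alignment."""
    cols = alignment.columns
    defects_central = 0
    defects_other_target = 0
    defects_other_decoy = 0
    seed_perfect = True
    run = best_run = 0

    for idx, col in enumerate(cols):
        if col.state.is_pair():
            run = 0
            continue
        if col.state == PairState.MISMATCH:
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
        pos = _assigned_position(cols, idx)
        if pos in CENTRAL_REGION:
            defects_central += 1
        else:
            defects_other_target += 1
            if pos not in SEED_REGION:
                defects_other_decoy += 1
        if pos in SEED_REGION and col.state != PairState.BULGE_TARGET:
            seed_perfect = False

    # indels adjacent to the 2-8 block break its perfect pairing
    for idx, col in enumerate(cols):
        if col.state != PairState.BULGE_TARGET:
            continue
        flank5 = _assigned_position(cols, idx)
        if flank5 in range(1, 9):  # bulge between i and i+1 with i in 1..8
            seed_perfect = False

    return RegionDiagnostics(
        defects_9_12=defects_central,
        perfect_2_8=seed_perfect,
        defects_other_target=defects_other_target,
        defects_other_decoy=defects_other_decoy,
        max_mismatch_run=best_run,
    )


def classify_diagnostics(diag: RegionDiagnostics) -> Verdict:
    """Pure rule application on precomputed diagnostics."""
    if (
        diag.defects_9_12 <= 1
        and diag.defects_other_target <= 4
        and diag.max_mismatch_run <= 1
    ):
        return Verdict.TARGET
    if (
        2 <= diag.defects_9_12 <= 5
        and diag.perfect_2_8
        and diag.defects_other_decoy <= 4
    ):
        return Verdict.DECOY
    return Verdict.NONE


def classify_interaction(alignment: DuplexAlignment) -> InteractionCall:
    diag = region_diagnostics(alignment)
    return InteractionCall(classify_diagnostics(diag), diag, alignment)


def classify_all(alignments: Sequence[DuplexAlignment]) -> list[InteractionCall]:
    return [classify_interaction(a) for a in alignments]


def write_call_table(calls: Sequence[InteractionCall], path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "mirna_id\ttranscript_id\tsite\tverdict\tdefects_9_12\t"
            "defects_other\tmax_mismatch_run\tmfe_ratio\n"
        )
        for call in calls:
            a = call.alignment
            d = call.diagnostics
            other = (
                d.defects_other_target
                if call.verdict is Verdict.TARGET
                else d.defects_other_decoy
            )
            handle.write(
                f"{a.mirna_id}\t{a.transcript_id}\t{a.site_start}-{a.site_end}\t"
                f"{call.verdict.value}\t{d.defects_9_12}\t{other}\t"
                f"{d.max_mismatch_run}\t{a.mfe_ratio:.15g}\n"
            )
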