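"""miRNA binding-site discovery by complementarity alignment and duplex MFE.

A miRNA is aligned antiparallel against a transcript (semi-global: the whole
miRNA must be covered, the transcript provides free flanks) with the scoring
match +1 / G:U +0.5 / mismatch -1 / gap open -2 / gap extend -1.  Each
retained site is scored with a nearest-neighbor hybridization free energy
(Watson-Crick stacks from the Xia/Turner RNA parameter set; simplified wobble
stack terms; length-dependent loop and bulge penalties) and the
site-to-perfect MFE ratio.  Columns are ordered by miRNA position 1..L (the 5'
end of the miRNA first); because the duplex is antiparallel, transcript
coordinates decrease along that order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .seq_io import MatureMiRNA, Transcript, ValidationError, revcomp_rna

log = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


class PairState(Enum):
    WC = "WC"
    GU = "GU"
    MISMATCH = "MISMATCH"
    BULGE_MIRNA = "BULGE_MIRNA"    # unpaired miRNA base
    BULGE_TARGET = "BULGE_TARGET"  # unpaired transcript base

    def is_pair(self) -> bool:
        return self in (PairState.WC, PairState.GU)


@dataclass(frozen=True)
class AlignmentColumn:
    mirna_pos: int | None       # 1..L, 1 = miRNA 5' end; None for BULGE_TARGET
    transcript_pos: int | None  # 1-based; None for BULGE_MIRNA
    state: PairState


@dataclass(frozen=True)
class DuplexAlignment:
    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    columns: tuple[AlignmentColumn, ...]
    mfe_site: float
    mfe_perfect: float
    mfe_ratio: float

    def __post_init__(self) -> None:
        mpos = [c.mirna_pos for c in self.columns if c.mirna_pos is not None]
        if mpos != list(range(1, len(mpos) + 1)):
            raise ValidationError("miRNA positions must appear exactly once, in order")
        tpos = [c.transcript_pos for c in self.columns if c.transcript_pos is not None]
        if any(b >= a for a, b in zip(tpos, tpos[1:])):
            raise ValidationError(
                "transcript positions must be strictly monotone along the duplex"
            )
        if self.site_start != min(tpos) or self.site_end != max(tpos):
            raise ValidationError("site_start/site_end must equal min/max coords")
        if self.mfe_site > 0:
            raise ValidationError("mfe_site must be <= 0")
        if self.mfe_perfect >= 0:
            raise ValidationError("mfe_perfect must be < 0")
        if not 0 < self.mfe_ratio <= 1:
            raise ValidationError("mfe_ratio must lie in (0, 1]")

    @property
    def mirna_length(self) -> int:
        return max(c.mirna_pos for c in self.columns if c.mirna_pos is not None)

    def alignment_string(self) -> str:
        """Three-line text rendering (miRNA 5'->3' / pairing / site 3'->5')."""
        top, mid, bot = [], [], []
        for col in self.columns:
            top.append("-" if col.mirna_pos is None else "*")
            bot.append("-" if col.transcript_pos is None else "*")
            mid.append(
                {"WC": "|", "GU": "o"}.get(col.state.value, " ")
                if col.state.is_pair()
                else " "
            )
        return "".join(top) + "/" + "".join(mid) + "/" + "".join(bot)


@dataclass(frozen=True)
class ScanParams:
    mfe_ratio_cutoff: float = 0.65
    max_defects_total: int = 10
    gu_counts_as_pair: bool = True
    report_overlapping: bool = False
    match_score: float = 1.0
    gu_score: float = 0.5
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_alignment_score: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mfe_ratio_cutoff <= 1:
            raise ValidationError("mfe_ratio_cutoff must lie in (0, 1]")
        if self.max_defects_total < 0:
            raise ValidationError("max_defects_total must be >= 0")


# ---------------------------------------------------------------------------
# Base pairing
# ---------------------------------------------------------------------------

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_state(mirna_base: str, target_base: str, gu_is_pair: bool = True) -> PairState:
    """Pair state of one miRNA base against one transcript base."""
    pair = (mirna_base, target_base)
    if pair in _WC:
        return PairState.WC
    if pair in _WOBBLE:
        return PairState.GU if gu_is_pair else PairState.MISMATCH
    return PairState.MISMATCH


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"non-RNA base {exc.args[0]!r} in sequence") from None


def _pair_score_matrix(params: ScanParams) -> np.ndarray:
    mat = np.full((4, 4), params.mismatch_score, dtype=np.float64)
    for a, b in _WC:
        mat[_ENC[a], _ENC[b]] = params.match_score
    gu = params.gu_score if params.gu_counts_as_pair else params.mismatch_score
    for a, b in _WOBBLE:
        mat[_ENC[a], _ENC[b]] = gu
    return mat


# ---------------------------------------------------------------------------
# Nearest-neighbor energy model
# ---------------------------------------------------------------------------

DUPLEX_INITIATION = 4.09  # kcal/mol

# Watson-Crick / Watson-Crick stacks, Xia et al. dG37 values.  Key is
# (x1, y1, x2, y2): pair x1:y1 stacked 5'-ward of pair x2:y2 on the top
# (miRNA) strand, i.e. 5'-x1 x2-3' over 3'-y1 y2-5'.
_WC_STACKS_CANONICAL = {
    ("A", "U", "A", "U"): -0.93,  # 5'AA3'/3'UU5'
    ("A", "U", "U", "A"): -1.10,  # 5'AU3'/3'UA5'
    ("U", "A", "A", "U"): -1.33,  # 5'UA3'/3'AU5'
    ("C", "G", "U", "A"): -2.08,  # 5'CU3'/3'GA5'
    ("C", "G", "A", "U"): -2.11,  # 5'CA3'/3'GU5'
    ("G", "C", "U", "A"): -2.24,  # 5'GU3'/3'CA5'
    ("G", "C", "A", "U"): -2.35,  # 5'GA3'/3'CU5'
    ("C", "G", "G", "C"): -2.36,  # 5'CG3'/3'GC5'
    ("G", "C", "G", "C"): -3.26,  # 5'GG3'/3'CC5'
    ("G", "C", "C", "G"): -3.42,  # 5'GC3'/3'CG5'
}

# Simplified wobble stack terms (Turner-lineage magnitudes, order-symmetric,
# clamped <= 0 so that losing a pair can never lower the duplex energy).
_GU_STACK_BY_PAIRSET = {
    frozenset([("A", "U"), ("G", "U")]): -1.3,
    frozenset([("U", "A"), ("G", "U")]): -1.0,
    frozenset([("A", "U"), ("U", "G")]): -1.4,
    frozenset([("U", "A"), ("U", "G")]): -1.2,
    frozenset([("G", "C"), ("G", "U")]): -2.1,
    frozenset([("C", "G"), ("G", "U")]): -1.5,
    frozenset([("G", "C"), ("U", "G")]): -2.2,
    frozenset([("C", "G"), ("U", "G")]): -1.4,
    frozenset([("G", "U")]): -0.5,
    frozenset([("G", "U"), ("U", "G")]): -0.6,
    frozenset([("U", "G")]): -0.5,
}


def _build_stack_table() -> dict[tuple[str, str, str, str], float]:
    table: dict[tuple[str, str, str, str], float] = {}
    for (x1, y1, x2, y2), dg in _WC_STACKS_CANONICAL.items():
        table[(x1, y1, x2, y2)] = dg
        # 180-degree rotation of the duplex leaves the stack unchanged
        table[(y2, x2, y1, x1)] = dg
    pairs = list(_WC) + list(_WOBBLE)
    for p1 in pairs:
        for p2 in pairs:
            if p1 in _WOBBLE or p2 in _WOBBLE:
                dg = _GU_STACK_BY_PAIRSET[frozenset([p1, p2])]
                table[(p1[0], p1[1], p2[0], p2[1])] = dg
    return table


STACK_TABLE = _build_stack_table()

# loop penalties (kcal/mol); positive = destabilizing
_INTERNAL_11 = 1.7            # single mismatch (1x1 internal loop)
_INTERNAL_BASE = 2.1
_INTERNAL_PER_NT = 0.45
_BULGE_BASE = 3.1
_BULGE_PER_NT = 0.55
_TERMINAL_PER_NT = 0.5


def _loop_penalty(n_mirna_nt: int, n_target_nt: int, terminal: bool) -> float:
    total = n_mirna_nt + n_target_nt
    if total == 0:
        return 0.0
    if terminal:
        return _TERMINAL_PER_NT * total
    if n_mirna_nt == 0 or n_target_nt == 0:
        return _BULGE_BASE + _BULGE_PER_NT * (total - 1)
    if n_mirna_nt == 1 and n_target_nt == 1:
        return _INTERNAL_11
    return _INTERNAL_BASE + _INTERNAL_PER_NT * total


def hybrid_mfe(
    columns: Sequence[AlignmentColumn],
    mirna_seq: str,
    transcript_seq: str,
) -> float:
    """Nearest-neighbor duplex free energy of an alignment, in kcal/mol.

    Sums stacking terms over adjacent paired columns, adds the duplex
    initiation penalty and a length-dependent penalty per defect run
    (mismatch, internal loop, or bulge; runs at the duplex ends are charged a
    light per-nucleotide term).  More negative = more stable.
    """
    paired = [c for c in columns if c.state.is_pair()]
    if not paired:
        raise ValidationError("hybrid_mfe: alignment has no paired columns")

    def bases(col: AlignmentColumn) -> tuple[str, str]:
        return (
            mirna_seq[col.mirna_pos - 1],
            transcript_seq[col.transcript_pos - 1],
        )

    energy = DUPLEX_INITIATION
    prev_pair_idx: int | None = None
    cols = list(columns)
    for i, col in enumerate(cols):
        if not col.state.is_pair():
            continue
        if prev_pair_idx is not None:
            gap_cols = cols[prev_pair_idx + 1 : i]
            if not gap_cols:
                x1, y1 = bases(cols[prev_pair_idx])
                x2, y2 = bases(col)
                energy += STACK_TABLE[(x1, y1, x2, y2)]
            else:
                n_m = sum(
                    1 for c in gap_cols
                    if c.state in (PairState.MISMATCH, PairState.BULGE_MIRNA)
                )
                n_t = sum(
                    1 for c in gap_cols
                    if c.state in (PairState.MISMATCH, PairState.BULGE_TARGET)
                )
                energy += _loop_penalty(n_m, n_t, terminal=False)
        prev_pair_idx = i

    first_pair = next(i for i, c in enumerate(cols) if c.state.is_pair())
    last_pair = max(i for i, c in enumerate(cols) if c.state.is_pair())
    for run in (cols[:first_pair], cols[last_pair + 1 :]):
        n_m = sum(1 for c in run if c.state in (PairState.MISMATCH, PairState.BULGE_MIRNA))
        n_t = sum(1 for c in run if c.state in (PairState.MISMATCH, PairState.BULGE_TARGET))
        energy += _loop_penalty(n_m, n_t, terminal=True)
    return energy


def perfect_duplex_columns(mirna_seq: str) -> tuple[AlignmentColumn, ...]:
    """All-WC columns of a miRNA against its exact reverse complement."""
    length = len(mirna_seq)
    return tuple(
        AlignmentColumn(p, length - p + 1, PairState.WC)
        for p in range(1, length + 1)
    )


def perfect_mfe(mirna: MatureMiRNA | str) -> float:
    """MFE of the miRNA bound to a perfectly complementary site."""
    seq = mirna.sequence if isinstance(mirna, MatureMiRNA) else seq_check(mirna)
    site = revcomp_rna(seq)
    value = hybrid_mfe(perfect_duplex_columns(seq), seq, site)
    if value >= 0:
        raise ValidationError("perfect_mfe must be negative")
    return value


def seq_check(seq: str) -> str:
    if not seq or set(seq) - set("ACGU"):
        raise ValidationError(f"invalid RNA sequence {seq!r}")
    return seq


def mfe_ratio(mfe_site: float, mfe_perfect: float) -> float:
    """MFEsite / MFEperfect, full floating precision."""
    if mfe_perfect >= 0:
        raise ValidationError("mfe_perfect must be < 0")
    if mfe_site > 0:
        raise ValidationError("mfe_site must be <= 0")
    return mfe_site / mfe_perfect


# ---------------------------------------------------------------------------
# Semi-global Gotoh alignment kernel
# ---------------------------------------------------------------------------

NEG = -1e30


@njit(cache=False)
def _gotoh_fill(a, t, score_mat, gap_open, gap_extend):  # pragma: no cover - numba
    m = a.shape[0]
    n = t.shape[0]
    M = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)  # gap in transcript (miRNA base unpaired)
    Iy = np.full((m + 1, n + 1), NEG)  # gap in miRNA (transcript base unpaired)
    for j in range(n + 1):
        M[0, j] = 0.0
    Ix[1, 0] = gap_open
    for i in range(2, m + 1):
        Ix[i, 0] = Ix[i - 1, 0] + gap_extend
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = score_mat[ai, t[j - 1]]
            best_prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best_prev:
                best_prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best_prev:
                best_prev = Iy[i - 1, j - 1]
            M[i, j] = best_prev + s
            x = M[i - 1, j] + gap_open
            if Ix[i - 1, j] + gap_extend > x:
                x = Ix[i - 1, j] + gap_extend
            Ix[i, j] = x
            y = M[i, j - 1] + gap_open
            if Iy[i, j - 1] + gap_extend > y:
                y = Iy[i, j - 1] + gap_extend
            Iy[i, j] = y
    return M, Ix, Iy


def _traceback(M, Ix, Iy, a_len, end_j, state, score_mat, a, t, gap_open, gap_extend):
    """Walk pointers from (a_len, end_j); returns list of (i or 0, j or 0, kind)."""
    steps: list[tuple[int, int, str]] = []
    i, j = a_len, end_j
    eps = 1e-9
    while i > 0:
        if state == 0:  # M: consumed a[i-1] and t[j-1]
            steps.append((i, j, "M"))
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if i == 1:
                state = 0
                i, j = i - 1, j - 1
                break
            if abs(M[i - 1, j - 1] - prev) < eps:
                state = 0
            elif abs(Ix[i - 1, j - 1] - prev) < eps:
                state = 1
            else:
                state = 2
            i, j = i - 1, j - 1
        elif state == 1:  # Ix: consumed a[i-1] only
            steps.append((i, 0, "X"))
            if abs(Ix[i, j] - (M[i - 1, j] + gap_open)) < eps:
                state = 0
            else:
                state = 1
            i -= 1
        else:  # Iy: consumed t[j-1] only
            steps.append((0, j, "Y"))
            if abs(Iy[i, j] - (M[i, j - 1] + gap_open)) < eps:
                state = 0
            else:
                state = 2
            j -= 1
    steps.reverse()
    return steps


def scan_candidate_sites(
    mirna: MatureMiRNA,
    transcript: Transcript,
    params: ScanParams = ScanParams(),
) -> list[DuplexAlignment]:
    """Find candidate miRNA binding sites on a transcript.

    The reverse complement of the miRNA is aligned against the transcript
    (semi-global; all miRNA positions covered), each candidate end position is
    traced back, per-column pair states are derived by re-pairing the miRNA
    5'->3' against the antiparallel site, and sites are annotated with
    mfe_site / mfe_perfect / mfe_ratio.  Sites below the MFEratio cutoff or
    with more than ``max_defects_total`` defects are discarded; overlapping
    sites are collapsed to the best ratio unless ``report_overlapping``.
    Output is sorted by mfe_ratio descending, ties by site_start ascending.
    """
    if not mirna.sequence or not transcript.sequence:
        raise ValidationError("empty sequence")
    if len(transcript) < len(mirna):
        raise ValidationError(
            f"transcript {transcript.id!r} shorter than miRNA {mirna.id!r}"
        )
    mseq = mirna.sequence
    length = len(mseq)
    # transcript runs 5'->3' left to right; the miRNA anneals antiparallel, so
    # left-to-right transcript order pairs miRNA positions L..1
    a = encode(mseq[::-1])
    t = encode(transcript.sequence)
    score_mat = _pair_score_matrix(params)
    # score_mat is indexed [mirna_base, target_base]; the kernel sees the
    # reversed miRNA, whose entries are still miRNA bases, so no re-indexing
    M, Ix, Iy = _gotoh_fill(a, t, score_mat, params.gap_open, params.gap_extend)

    mfe_perf = perfect_mfe(mirna)
    candidates: list[DuplexAlignment] = []
    for end_j in range(1, len(t) + 1):
        end_score = max(M[length, end_j], Ix[length, end_j])
        if end_score < params.min_alignment_score:
            continue
        state = 0 if M[length, end_j] >= Ix[length, end_j] else 1
        steps = _traceback(
            M, Ix, Iy, length, end_j, state, score_mat, a, t,
            params.gap_open, params.gap_extend,
        )
        columns = []
        for i, j, kind in steps:
            if kind == "M":
                mpos = length - i + 1  # a is the reversed miRNA
                st = pair_state(
                    mseq[mpos - 1], transcript.sequence[j - 1],
                    params.gu_counts_as_pair,
                )
                columns.append(AlignmentColumn(mpos, j, st))
            elif kind == "X":
                mpos = length - i + 1
                columns.append(AlignmentColumn(mpos, None, PairState.BULGE_MIRNA))
            else:
                columns.append(AlignmentColumn(None, j, PairState.BULGE_TARGET))
        # reorder by miRNA position 1..L (transcript coords then decrease)
        columns.reverse()
        defects = sum(1 for c in columns if not c.state.is_pair())
        if defects > params.max_defects_total:
            continue
        if not any(c.state.is_pair() for c in columns):
            continue
        mfe_site = hybrid_mfe(columns, mseq, transcript.sequence)
        if mfe_site > 0:
            continue
        ratio = mfe_ratio(mfe_site, mfe_perf)
        if ratio < params.mfe_ratio_cutoff:
            continue
        tpos = [c.transcript_pos for c in columns if c.transcript_pos is not None]
        candidates.append(
            DuplexAlignment(
                mirna_id=mirna.id,
                transcript_id=transcript.id,
                site_start=min(tpos),
                site_end=max(tpos),
                columns=tuple(columns),
                mfe_site=mfe_site,
                mfe_perfect=mfe_perf,
                mfe_ratio=ratio,
            )
        )

    candidates.sort(key=lambda d: (-d.mfe_ratio, d.site_start, d.site_end))
    if params.report_overlapping:
        return candidates
    kept: list[DuplexAlignment] = []
    for cand in candidates:
        if all(
            cand.site_end < k.site_start or cand.site_start > k.site_end
            for k in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda d: (-d.mfe_ratio, d.site_start))
    return kept


def scan_all(
    mirnas: Sequence[MatureMiRNA],
    transcripts: Sequence[Transcript],
    params: ScanParams = ScanParams(),
) -> list[DuplexAlignment]:
    """Scan every miRNA against every transcript long enough to host it."""
    out: list[DuplexAlignment] = []
    for tx in transcripts:
        for mi in mirnas:
            if len(tx) < len(mi):
                continue
            out.extend(scan_candidate_sites(mi, tx, params))
    return out


def write_alignment_table(alignments: Sequence[DuplexAlignment], path) -> None:
    """TSV of alignments mirroring the published table columns."""
    with open(path, "w") as handle:
        handle.write(
            "mirna_id\ttranscript_id\tsite\tmfe_perfect\tmfe_site\tmfe_ratio\t"
            "alignment\n"
        )
        for aln in alignments:
            handle.write(
                f"{aln.mirna_id}\t{aln.transcript_id}\t"
                f"{aln.site_start}-{aln.site_end}\t{aln.mfe_perfect:.2f}\t"
                f"{aln.mfe_site:.2f}\t{aln.mfe_ratio:.15g}\t"
                f"{aln.alignment_string()}\n"
            )
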