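"""Cross-species conservation of miRNA-pairing regions.

Workflow: cut a fixed-width window around a binding site, find homologous
regions in other genomes with a seed-and-extend search under a Karlin-Altschul
E-value cutoff, align the collected windows, and call the site conserved when
its mean per-column identity to the reference exceeds a threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .seq_io import Transcript, ValidationError, normalize_rna, revcomp_rna

log = logging.getLogger(__name__)

# frozen search constants: exact seed word size, ungapped +1/-2 scoring and
# Karlin-Altschul parameters for that scoring system
SEED_LENGTH = 7
MATCH = 1.0
MISMATCH = -2.0
XDROP = 10.0
KA_LAMBDA = 1.33
KA_K = 0.621


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int  # 1-based inclusive, always on the plus strand
    subject_end: int
    strand: str
    score: float
    percent_identity: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError("e_value must be >= 0")
        if self.subject_start > self.subject_end:
            raise ValidationError("subject_start must be <= subject_end")


@dataclass(frozen=True)
class WindowExtract:
    sequence: str
    window_start: int  # 1-based transcript coords
    window_end: int
    site_offset_start: int  # 1-based offsets of the site within the window
    site_offset_end: int
    clipped_left: int   # bases lost to the transcript 5' end
    clipped_right: int
    site_exceeds_window: bool = False


@dataclass
class SiteAlignmentBlock:
    ids: list[str]
    rows: list[str]           # aligned sequences, reference first
    site_columns: list[int]   # 0-based column indices of the reference site

    def __post_init__(self) -> None:
        if len(set(len(r) for r in self.rows)) != 1:
            raise ValidationError("alignment rows must have equal length")
        width = len(self.rows[0])
        if any(c < 0 or c >= width for c in self.site_columns):
            raise ValidationError("site_columns out of bounds")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def column_frequencies(self) -> list[dict[str, int]]:
        """Per-column base/gap counts (sequence-logo ready)."""
        freqs = []
        for col in range(self.width):
            counts: dict[str, int] = {}
            for row in self.rows:
                counts[row[col]] = counts.get(row[col], 0) + 1
            freqs.append(counts)
        return freqs


@dataclass(frozen=True)
class ConservationReport:
    site_identity: float
    flank_identity: float
    conserved: bool
    n_rows: int


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_site_window(
    transcript: Transcript | str,
    site_start: int,
    site_end: int,
    total_len: int = 100,
) -> WindowExtract:
    """Window of ``total_len`` centered on the site, clamped at transcript ends.

    The left flank takes the floor of the remaining length, the right flank
    the ceiling; overflow at one transcript end is redistributed to the other
    side when room exists, and the raw per-side overflow is reported in
    ``clipped_left`` / ``clipped_right``.  If the site is longer than
    ``total_len`` the window is the site itself and ``site_exceeds_window``
    is set.
    """
    seq = transcript.sequence if isinstance(transcript, Transcript) else transcript
    n = len(seq)
    if not 1 <= site_start <= site_end <= n:
        raise ValidationError(
            f"site {site_start}-{site_end} outside transcript of length {n}"
        )
    site_len = site_end - site_start + 1
    if site_len > total_len:
        log.warning("site length %d exceeds window %d", site_len, total_len)
        return WindowExtract(
            seq[site_start - 1 : site_end], site_start, site_end,
            1, site_len, 0, 0, site_exceeds_window=True,
        )
    remainder = total_len - site_len
    left = remainder // 2
    right = remainder - left
    want_start = site_start - left
    want_end = site_end + right
    clipped_left = max(0, 1 - want_start)
    clipped_right = max(0, want_end - n)
    start, end = want_start, want_end
    if start < 1:
        end = min(n, end + (1 - start))
        start = 1
    if end > n:
        start = max(1, start - (end - n))
        end = n
    return WindowExtract(
        sequence=seq[start - 1 : end],
        window_start=start,
        window_end=end,
        site_offset_start=site_start - start + 1,
        site_offset_end=site_end - start + 1,
        clipped_left=clipped_left,
        clipped_right=clipped_right,
    )


# ---------------------------------------------------------------------------
# Seed-and-extend homology search
# ---------------------------------------------------------------------------

def _extend_ungapped(query: str, subject: str, qpos: int, spos: int):
    """X-drop ungapped extension of an exact seed; returns (qs, qe, ss, se, score).

    Coordinates are 0-based half-open over the extended segment.
    """
    score = float(SEED_LENGTH) * MATCH
    # right extension
    best = score
    best_right = 0
    i = 0
    while (
        qpos + SEED_LENGTH + i < len(query)
        and spos + SEED_LENGTH + i < len(subject)
    ):
        score += MATCH if query[qpos + SEED_LENGTH + i] == subject[spos + SEED_LENGTH + i] else MISMATCH
        i += 1
        if score > best:
            best, best_right = score, i
        if best - score > XDROP:
            break
    score = best
    # left extension
    best_left = 0
    i = 0
    run = score
    while qpos - 1 - i >= 0 and spos - 1 - i >= 0:
        run += MATCH if query[qpos - 1 - i] == subject[spos - 1 - i] else MISMATCH
        i += 1
        if run > score:
            score, best_left = run, i
        if score - run > XDROP:
            break
    qs = qpos - best_left
    qe = qpos + SEED_LENGTH + best_right
    return qs, qe, spos - best_left, spos + SEED_LENGTH + best_right, score


def homology_search(
    query: str | Transcript,
    subject: str | Transcript,
    evalue_cutoff: float = 0.1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[HomologyHit]:
    """Seed-and-extend search of a query window against a subject sequence.

    Exact seeds of length 7 on both strands are extended ungapped with an
    X-drop rule under +1/-2 scoring; E = K*m*n*exp(-lambda*S) with the frozen
    constants above.  Hits with E < ``evalue_cutoff`` are returned sorted by
    E-value ascending.
    """
    if isinstance(query, Transcript):
        query_id, query = query.id, query.sequence
    if isinstance(subject, Transcript):
        subject_id, subject = subject.id, subject.sequence
    query = normalize_rna(query)
    subject = normalize_rna(subject)
    if len(query) < 11:
        raise ValidationError("query must be at least 11 nt")
    if not subject:
        return []

    m, n = len(query), len(subject)
    subject_index: dict[str, list[int]] = {}
    for j in range(n - SEED_LENGTH + 1):
        subject_index.setdefault(subject[j : j + SEED_LENGTH], []).append(j)

    hits: dict[tuple, HomologyHit] = {}
    for strand in "+-":
        q = query if strand == "+" else revcomp_rna(query)
        for i in range(m - SEED_LENGTH + 1):
            for j in subject_index.get(q[i : i + SEED_LENGTH], ()):
                qs, qe, ss, se, score = _extend_ungapped(q, subject, i, j)
                evalue = KA_K * m * n * math.exp(-KA_LAMBDA * score)
                if evalue >= evalue_cutoff:
                    continue
                matches = sum(
                    1 for a, b in zip(q[qs:qe], subject[ss:se]) if a == b
                )
                if strand == "+":
                    q_start, q_end = qs + 1, qe
                else:  # report plus-strand query coordinates
                    q_start, q_end = m - qe + 1, m - qs
                hit = HomologyHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    query_start=q_start,
                    query_end=q_end,
                    subject_start=ss + 1,
                    subject_end=se,
                    strand=strand,
                    score=score,
                    percent_identity=100.0 * matches / (qe - qs),
                    e_value=evalue,
                )
                key = (q_start, q_end, ss + 1, se, strand)
                if key not in hits or hit.score > hits[key].score:
                    hits[key] = hit
    out = sorted(hits.values(), key=lambda h: (h.e_value, h.subject_start, h.strand))
    return out


def hit_window_sequence(hit: HomologyHit, subject: str, total_len: int = 100) -> str:
    """Subject window around a hit, reverse-complemented for minus-strand hits."""
    window = extract_site_window(
        subject, hit.subject_start, hit.subject_end, total_len
    )
    seq = window.sequence
    return revcomp_rna(seq) if hit.strand == "-" else seq


# ---------------------------------------------------------------------------
# Multiple alignment (center-star progressive fallback for MAFFT)
# ---------------------------------------------------------------------------

def _pairwise_global(ref: str, other: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    aln = aligner.align(ref, other)[0]
    return str(aln[0]), str(aln[1])


def multiple_align(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    site_range: tuple[int, int] | None = None,
) -> SiteAlignmentBlock:
    """Center-star progressive global alignment; the first sequence is the
    reference and appears as the first row.

    Each other sequence is aligned to the reference pairwise (match +1 /
    mismatch -1 / gap -2), in descending order of identity to it, and merged
    under a once-a-gap-always-a-gap rule.  ``site_range`` gives the 1-based
    inclusive site offsets within the reference and is projected through
    reference gaps into ``site_columns``.
    """
    if len(sequences) < 2:
        raise ValidationError("multiple_align requires at least 2 sequences")
    sequences = [normalize_rna(s) for s in sequences]
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    ref = sequences[0]

    pairwise = []
    for idx in range(1, len(sequences)):
        ref_row, other_row = _pairwise_global(ref, sequences[idx])
        ident = sum(1 for a, b in zip(ref_row, other_row) if a == b) / len(ref_row)
        pairwise.append((idx, ref_row, other_row, ident))
    pairwise.sort(key=lambda x: (-x[3], x[0]))

    # per-alignment insertion counts between reference positions
    def insertion_profile(ref_row: str) -> list[int]:
        ins = [0] * (len(ref) + 1)
        k = 0
        for ch in ref_row:
            if ch == "-":
                ins[k] += 1
            else:
                k += 1
        return ins

    profiles = {idx: insertion_profile(r) for idx, r, _o, _i in pairwise}
    master = [0] * (len(ref) + 1)
    for prof in profiles.values():
        for k, v in enumerate(prof):
            master[k] = max(master[k], v)

    def pad_row(ref_row: str, other_row: str) -> str:
        out = []
        k = 0
        # walk the pairwise alignment, regrouping the other row into segments
        seg: list[str] = [""] * (len(ref) + 1)  # insertions before ref pos k
        chars: list[str] = [""] * len(ref)      # char opposite ref pos k
        for rc, oc in zip(ref_row, other_row):
            if rc == "-":
                seg[k] += oc
            else:
                chars[k] = oc
                k += 1
        for k in range(len(ref)):
            out.append(seg[k].ljust(master[k], "-"))
            out.append(chars[k])
        out.append(seg[len(ref)].ljust(master[len(ref)], "-"))
        return "".join(out)

    ref_aligned_parts = []
    for k in range(len(ref)):
        ref_aligned_parts.append("-" * master[k])
        ref_aligned_parts.append(ref[k])
    ref_aligned_parts.append("-" * master[len(ref)])
    rows = [("".join(ref_aligned_parts))]
    out_ids = [ids[0]]
    for idx, ref_row, other_row, _ident in pairwise:
        rows.append(pad_row(ref_row, other_row))
        out_ids.append(ids[idx])

    # map reference positions (1-based) to block columns
    col_of_ref = []
    col = 0
    for k in range(len(ref)):
        col += master[k]
        col_of_ref.append(col)
        col += 1
    if site_range is None:
        site_columns = list(range(len(rows[0])))
    else:
        lo, hi = site_range
        if not 1 <= lo <= hi <= len(ref):
            raise ValidationError("site_range outside the reference sequence")
        site_columns = col_of_ref[lo - 1 : hi]
    return SiteAlignmentBlock(ids=out_ids, rows=rows, site_columns=site_columns)


# ---------------------------------------------------------------------------
# Conservation call
# ---------------------------------------------------------------------------

def site_conservation(
    block: SiteAlignmentBlock,
    threshold: float = 0.80,
    method: str = "reference",
) -> ConservationReport:
    """Identity of site columns versus flank columns; conserved when the mean
    site identity exceeds the threshold.

    ``method='reference'`` (default): per-column identity is the fraction of
    non-reference rows matching the reference base (a gap never matches).
    ``method='pairwise'``: mean identity over all row pairs per column.
    """
    if len(block.rows) < 2:
        raise ValidationError("need at least 2 rows")
    if not block.site_columns:
        raise ValidationError("empty site_columns")
    if method not in ("reference", "pairwise"):
        raise ValidationError(f"unknown identity method {method!r}")

    def column_identity(col: int) -> float:
        chars = [row[col] for row in block.rows]
        if method == "reference":
            ref = chars[0]
            others = chars[1:]
            if ref == "-":
                return 0.0
            return sum(1 for c in others if c == ref) / len(others)
        pairs = matches = 0
        for i in range(len(chars)):
            for j in range(i + 1, len(chars)):
                pairs += 1
                if chars[i] == chars[j] and chars[i] != "-":
                    matches += 1
        return matches / pairs

    site_set = set(block.site_columns)
    site_vals = [column_identity(c) for c in sorted(site_set)]
    flank_cols = [c for c in range(block.width) if c not in site_set]
    flank_vals = [column_identity(c) for c in flank_cols]
    site_identity = sum(site_vals) / len(site_vals)
    flank_identity = sum(flank_vals) / len(flank_vals) if flank_vals else 1.0
    return ConservationReport(
        site_identity=site_identity,
        flank_identity=flank_identity,
        conserved=site_identity > threshold,
        n_rows=len(block.rows),
    )


def write_frequency_matrix(block: SiteAlignmentBlock, path) -> None:
    """TSV column-frequency matrix (one row per column; logo-ready counts)."""
    alphabet = ["A", "C", "G", "U", "-"]
    with open(path, "w") as handle:
        handle.write("column\tin_site\t" + "\t".join(alphabet) + "\n")
        site = set(block.site_columns)
        for col, counts in enumerate(block.column_frequencies()):
            flag = "1" if col in site else "0"
            row = "\t".join(str(counts.get(b, 0)) for b in alphabet)
            handle.write(f"{col}\t{flag}\t{row}\n")


def write_alignment_fasta(block: SiteAlignmentBlock, path) -> None:
    with open(path, "w") as handle:
        for rid, row in zip(block.ids, block.rows):
            handle.write(f">{rid}\n{row}\n")
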