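"""Degradome (PARE) read processing, t-plots, and cleavage-site evidence.

Reads are adapter-clipped, length/N filtered and deduplicated; their 5' ends
are mapped onto transcripts to build per-position abundance profiles; the
signal at the predicted cleavage position (opposite miRNA position 10, with a
9-12 window fallback) is ranked into categories 0-4 and given a transparent
positional-empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .classify import InteractionCall, Verdict
from .duplex import DuplexAlignment
from .seq_io import Transcript, ValidationError, normalize_rna

log = logging.getLogger(__name__)


@dataclass
class DegradomeLibrary:
    library_id: str
    unique_reads: dict[str, int] = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.unique_reads)

    @property
    def n_total(self) -> int:
        return sum(self.unique_reads.values())


@dataclass
class DegradomeProfile:
    transcript_id: str
    abundance: dict[int, int] = field(default_factory=dict)  # 1-based pos -> count

    @property
    def total(self) -> int:
        return sum(self.abundance.values())

    def at(self, position: int) -> int:
        return self.abundance.get(position, 0)


@dataclass(frozen=True)
class CleavageEvidence:
    mirna_id: str
    transcript_id: str
    cleavage_position: int
    category: int
    p_value: float
    library_id: str

    def __post_init__(self) -> None:
        if self.category not in (0, 1, 2, 3, 4):
            raise ValidationError(f"category {self.category} outside 0-4")
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p_value {self.p_value} outside [0,1]")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _iter_read_sequences(path) -> Iterable[str]:
    fmt = "fastq" if str(path).lower().endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq)


def preprocess_degradome(
    reads: Iterable[str],
    adapter: str = "",
    min_len: int = 18,
    max_n_frac: float = 0.1,
    library_id: str = "library",
) -> DegradomeLibrary:
    """Clip the 3' adapter, filter by length and N content, deduplicate.

    The adapter is clipped at the first exact occurrence of its first 8 nt;
    reads shorter than ``min_len`` after clipping, or with an N fraction above
    ``max_n_frac``, are discarded.  Surviving reads are RNA-normalized and
    merged with counts.
    """
    if min_len < 1:
        raise ValidationError("min_len must be >= 1")
    key = normalize_rna(adapter)[:8] if adapter else ""
    lib = DegradomeLibrary(library_id)
    for raw in reads:
        seq = normalize_rna(raw)
        if key:
            cut = seq.find(key)
            if cut != -1:
                seq = seq[:cut]
        if len(seq) < min_len:
            continue
        if seq.count("N") / len(seq) > max_n_frac:
            continue
        lib.unique_reads[seq] = lib.unique_reads.get(seq, 0) + 1
    return lib


def read_degradome_file(path, **kwargs) -> DegradomeLibrary:
    """Preprocess a FASTA/FASTQ degradome file (see preprocess_degradome)."""
    kwargs.setdefault("library_id", str(path))
    return preprocess_degradome(_iter_read_sequences(path), **kwargs)


# ---------------------------------------------------------------------------
# Mapping and t-plots
# ---------------------------------------------------------------------------

def map_five_prime_ends(
    library: DegradomeLibrary, transcript: Transcript
) -> DegradomeProfile:
    """Sum read counts at the 1-based 5'-end position of every exact occurrence.

    Multi-mapping reads contribute their full count at each occurrence.
    """
    if not transcript.sequence:
        raise ValidationError("empty transcript")
    profile = DegradomeProfile(transcript.id)
    seq = transcript.sequence
    for read, count in library.unique_reads.items():
        start = seq.find(read)
        while start != -1:
            pos = start + 1
            profile.abundance[pos] = profile.abundance.get(pos, 0) + count
            start = seq.find(read, start + 1)
    return profile


def write_tplot(profile: DegradomeProfile, path, marked: int | None = None) -> None:
    """Two-column TSV (position, abundance); the marked position is flagged."""
    with open(path, "w") as handle:
        handle.write("position\tabundance\tmarked\n")
        for pos in sorted(profile.abundance):
            flag = "*" if pos == marked else ""
            handle.write(f"{pos}\t{profile.abundance[pos]}\t{flag}\n")


# ---------------------------------------------------------------------------
# Cleavage position
# ---------------------------------------------------------------------------

def predicted_cleavage_site(alignment: DuplexAlignment) -> int:
    """Transcript coordinate opposite miRNA position 10 (canonical cleavage)."""
    for col in alignment.columns:
        if col.mirna_pos == 10:
            if col.transcript_pos is None:
                raise ValidationError(
                    "miRNA position 10 is unpaired; use cleavage_window()"
                )
            return col.transcript_pos
    raise ValidationError("alignment does not cover miRNA position 10")


def cleavage_window(alignment: DuplexAlignment) -> list[int]:
    """Transcript coordinates opposite miRNA positions 9-12 (where paired)."""
    return [
        col.transcript_pos
        for col in alignment.columns
        if col.mirna_pos in (9, 10, 11, 12) and col.transcript_pos is not None
    ]


# ---------------------------------------------------------------------------
# Categories and p-values
# ---------------------------------------------------------------------------

def assign_category(profile: DegradomeProfile, position: int) -> int | None:
    """Cleavage category at a position, or None when there is no signal.

    With a = abundance at the position, M = maximum and med = median over
    occupied positions: a == 1 -> 4; a > 1 and a == M, M unique -> 0;
    a == M attained more than once -> 1; med < a < M -> 2; a <= med -> 3.
    """
    if not profile.abundance:
        raise ValidationError("empty degradome profile")
    a = profile.at(position)
    if a == 0:
        return None
    if a == 1:
        return 4
    values = list(profile.abundance.values())
    peak = max(values)
    med = median(values)
    if a == peak:
        return 0 if values.count(peak) == 1 else 1
    return 2 if a > med else 3


def cleavage_pvalue(
    profile: DegradomeProfile, position: int, transcript_length: int
) -> float:
    """Empirical site p-value: fraction of transcript positions at least as good.

    Counts the occupied positions whose category is <= the observed category
    and divides by the transcript length; unoccupied positions never qualify.
    """
    if transcript_length < 1:
        raise ValidationError("transcript_length must be >= 1")
    observed = assign_category(profile, position)
    if observed is None:
        raise ValidationError(f"no degradome signal at position {position}")
    qualifying = sum(
        1
        for pos in profile.abundance
        if assign_category(profile, pos) <= observed
    )
    return qualifying / transcript_length


# ---------------------------------------------------------------------------
# Validation of target calls
# ---------------------------------------------------------------------------

def validate_interactions(
    calls: Sequence[InteractionCall],
    libraries: Sequence[DegradomeLibrary],
    transcripts: Mapping[str, Transcript],
    use_window: bool = True,
) -> list[CleavageEvidence]:
    """Emit per-library cleavage evidence for every target call with signal.

    For each target call and library the degradome is mapped onto the
    transcript and the canonical cleavage position checked; when it carries no
    signal and ``use_window`` is set, the occupied position opposite miRNA
    positions 9-12 with the highest abundance (ties: smallest coordinate) is
    used instead.
    """
    evidence: list[CleavageEvidence] = []
    targets = [c for c in calls if c.verdict is Verdict.TARGET]
    profiles: dict[tuple[str, str], DegradomeProfile] = {}
    for call in targets:
        tx_id = call.alignment.transcript_id
        if tx_id not in transcripts:
            raise ValidationError(f"transcript {tx_id!r} not provided")
        tx = transcripts[tx_id]
        for lib in libraries:
            cache_key = (lib.library_id, tx_id)
            if cache_key not in profiles:
                profiles[cache_key] = map_five_prime_ends(lib, tx)
            profile = profiles[cache_key]
            if not profile.abundance:
                continue
            try:
                position = predicted_cleavage_site(call.alignment)
            except ValidationError:
                position = None
            if (position is None or profile.at(position) == 0) and use_window:
                window = [
                    p for p in cleavage_window(call.alignment) if profile.at(p) > 0
                ]
                if window:
                    position = max(window, key=lambda p: (profile.at(p), -p))
            if position is None or profile.at(position) == 0:
                continue
            category = assign_category(profile, position)
            p_value = cleavage_pvalue(profile, position, len(tx))
            evidence.append(
                CleavageEvidence(
                    mirna_id=call.alignment.mirna_id,
                    transcript_id=tx_id,
                    cleavage_position=position,
                    category=category,
                    p_value=p_value,
                    library_id=lib.library_id,
                )
            )
    return evidence


def write_evidence_table(evidence: Sequence[CleavageEvidence], path) -> None:
    """TSV with per-library category/p-value lists slashed per duplex."""
    grouped: dict[tuple[str, str, int], list[CleavageEvidence]] = {}
    for ev in evidence:
        grouped.setdefault(
            (ev.mirna_id, ev.transcript_id, ev.cleavage_position), []
        ).append(ev)
    with open(path, "w") as handle:
        handle.write(
            "mirna_id\ttranscript_id\tcleavage_position\tcategories\t"
            "p_values\tlibraries\n"
        )
        for (mirna, tx, pos), evs in sorted(grouped.items()):
            cats = "/".join(str(e.category) for e in evs)
            ps = "/".join(format(e.p_value, ".15g") for e in evs)
            libs = "/".join(e.library_id for e in evs)
            handle.write(f"{mirna}\t{tx}\t{pos}\t{cats}\t{ps}\t{libs}\n")
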