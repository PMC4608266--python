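"""Synthetic data generators with recorded ground truth for every stage.

All generators are pure functions of their parameters and seed.  Backgrounds
are uniform over {A,C,G,U}; implanted binding sites are built as the reverse
complement of the miRNA with controlled defects, mismatch substitutions always
pick a base that neither Watson-Crick nor wobble pairs the miRNA base, so an
intended defect can never silently become a pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .classify import Verdict, classify_diagnostics, region_diagnostics
from .degradome import DegradomeLibrary
from .duplex import (
    AlignmentColumn,
    DuplexAlignment,
    PairState,
    hybrid_mfe,
    mfe_ratio,
    perfect_mfe,
)
from .seq_io import (
    ExpressionMatrix,
    MatureMiRNA,
    Transcript,
    ValidationError,
    revcomp_rna,
)

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


@dataclass
class TruthRecord:
    kind: str                  # target_site | decoy_site | coexpression_pair |
                               # enriched_term | conserved_site
    ids: dict[str, str]
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "TruthRecord":
        return cls(**json.loads(line))


def write_truths(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as handle:
        for t in truths:
            handle.write(t.to_json() + "\n")


def read_truths(path) -> list[TruthRecord]:
    with open(path) as handle:
        return [TruthRecord.from_json(line) for line in handle if line.strip()]


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# miRNAs
# ---------------------------------------------------------------------------

def gen_mirnas(
    n: int,
    length_range: tuple[int, int] = (20, 22),
    seed: int = 0,
) -> list[MatureMiRNA]:
    """Uniform random mature miRNAs with ids syn-miR-0001, syn-miR-0002, ..."""
    lo, hi = length_range
    if not (1 <= n and 18 <= lo <= hi <= 26):
        raise ValidationError("need n >= 1 and 18 <= lo <= hi <= 26")
    rng = np.random.default_rng(seed)
    seqs: set[str] = set()
    out: list[MatureMiRNA] = []
    while len(out) < n:
        length = int(rng.integers(lo, hi + 1))
        seq = random_rna(rng, length)
        if seq in seqs:  # keep sequences unique so merging is a no-op
            continue
        seqs.add(seq)
        out.append(MatureMiRNA(f"syn-miR-{len(out) + 1:04d}", seq))
    return out


# ---------------------------------------------------------------------------
# Site implantation
# ---------------------------------------------------------------------------

def _non_pairing_base(
    rng: np.random.Generator, *mirna_bases: str, strict: bool = True
) -> str:
    """A base that pairs (WC or wobble) with none of the given miRNA bases.

    With ``strict=False`` (bulge insertions between two miRNA bases) the
    constraint is relaxed one flanking base at a time when no base avoids
    every partner, e.g. between G and U every base pairs with one of them.
    """
    bases = list(mirna_bases)
    while True:
        banned = set()
        for b in bases:
            banned.add(_WC_PARTNER[b])
            if b in _WOBBLE_PARTNER:
                banned.add(_WOBBLE_PARTNER[b])
        choices = [b for b in "ACGU" if b not in banned]
        if choices:
            return str(rng.choice(choices))
        if strict or not bases:
            raise ValidationError("no non-pairing base exists for this context")
        bases = bases[:-1]


def build_site(
    mirna: MatureMiRNA,
    defect_spec: Sequence[tuple[int, str]],
    rng: np.random.Generator,
) -> tuple[str, list[AlignmentColumn]]:
    """Construct a binding-site sequence and its intended alignment columns.

    ``defect_spec`` lists (miRNA position, defect type) with defect type one
    of MISMATCH, BULGE_MIRNA (delete the opposing site base) or BULGE_TARGET
    (insert an extra site base between positions p and p+1).  The site is
    returned 5'->3' in transcript orientation.
    """
    L = len(mirna.sequence)
    seen: set[int] = set()
    bulge_counts: dict[int, int] = {}
    spec: dict[int, str] = {}
    for pos, kind in defect_spec:
        if not 1 <= pos <= L:
            raise ValidationError(f"defect position {pos} outside 1..{L}")
        if kind not in ("MISMATCH", "BULGE_MIRNA", "BULGE_TARGET"):
            raise ValidationError(f"unknown defect type {kind!r}")
        if kind == "BULGE_TARGET":
            # repeated entries stack into a multi-nucleotide bulge after pos
            bulge_counts[pos] = bulge_counts.get(pos, 0) + 1
            continue
        if pos in seen:
            raise ValidationError(f"conflicting defects at position {pos}")
        seen.add(pos)
        spec[pos] = kind

    # build per-miRNA-position columns 1..L, then render the site 3'->5'
    # (transcript orientation reverses miRNA order)
    site_chars_rev: list[str] = []  # in miRNA order 1..L
    columns: list[AlignmentColumn] = []
    for pos in range(1, L + 1):
        base = mirna.sequence[pos - 1]
        kind = spec.get(pos)
        if kind == "BULGE_MIRNA":
            columns.append(AlignmentColumn(pos, None, PairState.BULGE_MIRNA))
        elif kind == "MISMATCH":
            # also avoid pairing the flanking miRNA bases where possible, so
            # a run of mismatches cannot realign as a shifted helix
            neighbors = []
            if pos < L:
                neighbors.append(mirna.sequence[pos])
            if pos > 1:
                neighbors.append(mirna.sequence[pos - 2])
            site_base = _non_pairing_base(rng, base, *neighbors, strict=False)
            site_chars_rev.append(site_base)
            columns.append(AlignmentColumn(pos, -1, PairState.MISMATCH))
        else:
            site_base = _WC_PARTNER[base]
            site_chars_rev.append(site_base)
            columns.append(AlignmentColumn(pos, -1, PairState.WC))
        n_bulge = bulge_counts.get(pos, 0)
        if n_bulge:
            if pos == L:
                raise ValidationError("BULGE_TARGET needs a 3'-ward miRNA position")
            # most-binding context first: relaxation drops the outer bases
            context = [base, mirna.sequence[pos]]
            if pos + 1 < L:
                context.append(mirna.sequence[pos + 1])
            if pos > 1:
                context.append(mirna.sequence[pos - 2])
            for _ in range(n_bulge):
                extra = _non_pairing_base(rng, *context, strict=False)
                site_chars_rev.append(extra)
                columns.append(AlignmentColumn(None, -1, PairState.BULGE_TARGET))

    site = "".join(reversed(site_chars_rev))
    return site, columns


def _materialize_columns(
    columns: Sequence[AlignmentColumn], site_start: int, site_len: int
) -> list[AlignmentColumn]:
    """Fill real transcript coordinates into placeholder columns."""
    out = []
    # walk in miRNA order; transcript coordinate runs from the site 3' end down
    coord = site_start + site_len - 1
    for col in columns:
        if col.transcript_pos is None:
            out.append(col)
        else:
            out.append(AlignmentColumn(col.mirna_pos, coord, col.state))
            coord -= 1
    return out


def implant_site(
    background: Transcript,
    mirna: MatureMiRNA,
    defect_spec: Sequence[tuple[int, str]],
    position: int,
    seed: int = 0,
) -> tuple[Transcript, TruthRecord]:
    """Overwrite a stretch of the background with a constructed binding site.

    ``position`` is the 1-based transcript coordinate of the site 5' end.  The
    intended verdict is computed with the classifier rules and recorded.
    """
    rng = np.random.default_rng(seed)
    site, columns = build_site(mirna, defect_spec, rng)
    if position < 1 or position + len(site) - 1 > len(background):
        raise ValidationError(
            f"site of length {len(site)} does not fit at {position} in "
            f"{background.id!r} (length {len(background)})"
        )
    seq = (
        background.sequence[: position - 1]
        + site
        + background.sequence[position - 1 + len(site) :]
    )
    tx = Transcript(background.id, seq, background.biotype)

    real_columns = _materialize_columns(columns, position, len(site))
    mfe_perf = perfect_mfe(mirna)
    # clamp: a wildly defective planted site may come out >= 0 kcal/mol, but
    # the alignment object requires a (small) negative site energy
    mfe_site = min(hybrid_mfe(real_columns, mirna.sequence, seq), -1e-9)
    alignment = DuplexAlignment(
        mirna_id=mirna.id,
        transcript_id=tx.id,
        site_start=position,
        site_end=position + len(site) - 1,
        columns=tuple(real_columns),
        mfe_site=mfe_site,
        mfe_perfect=mfe_perf,
        mfe_ratio=mfe_ratio(mfe_site, mfe_perf),
    )
    verdict = classify_diagnostics(region_diagnostics(alignment))
    kind = {
        Verdict.TARGET: "target_site",
        Verdict.DECOY: "decoy_site",
        Verdict.NONE: "null_site",
    }[verdict]
    cleavage = next(
        (c.transcript_pos for c in real_columns if c.mirna_pos == 10), None
    )
    truth = TruthRecord(
        kind=kind,
        ids={"mirna": mirna.id, "transcript": tx.id},
        params={
            "site_start": position,
            "site_end": position + len(site) - 1,
            "defects": [[p, k] for p, k in defect_spec],
            "verdict": verdict.value,
            "cleavage_position": cleavage,
            "mfe_ratio": alignment.mfe_ratio,
        },
        seed=seed,
    )
    return tx, truth


def _bulge_anchor_ok(mirna_seq: str, pos: int) -> bool:
    """True when some base pairs no miRNA base in positions pos-1..pos+2, so
    an inserted bulge cannot slide or pair into a shifted helix."""
    lo = max(1, pos - 1)
    hi = min(len(mirna_seq), pos + 2)
    banned = set()
    for b in mirna_seq[lo - 1 : hi]:
        banned.add(_WC_PARTNER[b])
        if b in _WOBBLE_PARTNER:
            banned.add(_WOBBLE_PARTNER[b])
    return len(banned) < 4


def random_decoy_spec(
    rng: np.random.Generator, mirna_seq: str
) -> list[tuple[int, str]]:
    """A rule-conformant decoy defect spec in classic target-mimic form.

    Either a 2-3 nt central bulge (inserted transcript bases between miRNA
    positions 9-12, at an anchor where a strictly non-pairing insertion base
    exists) or two non-adjacent central mismatches.  These structures are
    energy-mild (site/perfect MFE ratio stays above ~0.4) and
    realignment-stable, so the scanner can rediscover them exactly.
    """
    spec: list[tuple[int, str]]
    anchors = [p for p in (9, 10, 11) if _bulge_anchor_ok(mirna_seq, p)]
    if anchors and rng.random() < 0.5:
        pos = int(anchors[rng.integers(0, len(anchors))])
        spec = [(pos, "BULGE_TARGET")] * int(rng.integers(2, 4))
    else:
        pair = [(9, 11), (9, 12), (10, 12)][int(rng.integers(0, 3))]
        spec = [(pair[0], "MISMATCH"), (pair[1], "MISMATCH")]
    return spec


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def gen_transcriptome(
    mirnas: Sequence[MatureMiRNA],
    n_linc: int,
    n_mrna: int,
    site_plan: Sequence[tuple[int, int, Sequence[tuple[int, str]]]],
    mean_len: int = 500,
    seed: int = 0,
    margin_3p: int = 30,
) -> tuple[list[Transcript], list[TruthRecord]]:
    """Random-background transcripts with sites implanted per plan.

    ``site_plan`` entries are (transcript index, miRNA index, defect_spec);
    transcript indices 0..n_linc-1 are lincRNAs, the rest mRNAs.  Site
    positions are drawn at random without overlap on each transcript, keeping
    ``margin_3p`` bases clear at the 3' end so degradome reads starting at the
    cleavage position never overrun the transcript.
    """
    rng = np.random.default_rng(seed)
    n_total = n_linc + n_mrna
    lengths = np.maximum(
        120, rng.gamma(shape=6.0, scale=mean_len / 6.0, size=n_total).astype(int)
    )
    transcripts: list[Transcript] = []
    for i in range(n_total):
        biotype = "lincRNA" if i < n_linc else "mRNA"
        prefix = "syn-linc" if i < n_linc else "syn-mRNA"
        idx = i if i < n_linc else i - n_linc
        transcripts.append(
            Transcript(f"{prefix}-{idx + 1:04d}", random_rna(rng, int(lengths[i])),
                       biotype)
        )

    occupied: dict[int, list[tuple[int, int]]] = {}
    truths: list[TruthRecord] = []
    for tx_idx, mi_idx, defects in site_plan:
        tx = transcripts[tx_idx]
        mirna = mirnas[mi_idx]
        site_len = len(mirna) + sum(1 for _p, k in defects if k == "BULGE_TARGET") \
            - sum(1 for _p, k in defects if k == "BULGE_MIRNA")
        spans = occupied.setdefault(tx_idx, [])
        placed = False
        upper = len(tx) - site_len + 2 - margin_3p
        if upper < 2:
            upper = len(tx) - site_len + 2
        for _attempt in range(200):
            position = int(rng.integers(1, upper))
            span = (position, position + site_len - 1)
            if all(span[1] < s or span[0] > e for s, e in spans):
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"site density exceeds capacity of transcript {tx.id!r}"
            )
        site_seed = int(rng.integers(0, 2**31))
        tx_new, truth = implant_site(tx, mirna, defects, position, seed=site_seed)
        transcripts[tx_idx] = tx_new
        spans.append(span)
        truths.append(truth)
    return transcripts, truths


# ---------------------------------------------------------------------------
# Degradome
# ---------------------------------------------------------------------------

def gen_degradome(
    truths: Sequence[TruthRecord],
    transcripts: Sequence[Transcript],
    peak_reads: int = 10,
    noise_reads: int = 20,
    read_len: int = 20,
    seed: int = 0,
    library_id: str = "syn-degradome",
) -> DegradomeLibrary:
    """Reads with 5' ends piled at each planted cleavage position plus uniform
    background noise; every read is an exact transcript substring."""
    rng = np.random.default_rng(seed)
    by_id = {t.id: t for t in transcripts}
    lib = DegradomeLibrary(library_id)

    def add_read(tx: Transcript, start: int) -> None:
        # clip the 5' position back if the read would overrun the 3' end
        start = max(1, min(start, len(tx) - read_len + 1))
        read = tx.sequence[start - 1 : start - 1 + read_len]
        lib.unique_reads[read] = lib.unique_reads.get(read, 0) + 1

    for truth in truths:
        if truth.kind != "target_site":
            continue
        tx = by_id[truth.ids["transcript"]]
        cleavage = truth.params["cleavage_position"]
        if cleavage is None:
            continue
        for _ in range(peak_reads):
            add_read(tx, cleavage)
        for _ in range(noise_reads):
            add_read(tx, int(rng.integers(1, len(tx) - read_len + 2)))
    return lib


# ---------------------------------------------------------------------------
# Expression matrices with planted modules
# ---------------------------------------------------------------------------

def gen_expression_with_modules(
    n_genes: int,
    n_samples: int = 30,
    modules: Sequence[Sequence[str]] = (),
    r_target: float = 0.9,
    seed: int = 0,
    gene_prefix: str = "gene",
) -> tuple[ExpressionMatrix, list[TruthRecord]]:
    """Expression matrix whose module members share a latent factor.

    Module members are sqrt(r)*factor + sqrt(1-r)*noise, which gives pairwise
    expected correlation ~ r_target; the affine shift to an FPKM-like scale
    preserves correlations.  Named module genes not among the generated ids
    are appended.  Remaining genes are independent noise.
    """
    if n_samples < 4:
        raise ValidationError("n_samples must be >= 4")
    flat = [g for mod in modules for g in mod]
    if len(flat) != len(set(flat)):
        raise ValidationError("module memberships must be disjoint")
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}-{i + 1:05d}" for i in range(n_genes)]
    extra = [g for g in flat if g not in set(genes)]
    genes = genes + extra
    index = {g: i for i, g in enumerate(genes)}

    latent = rng.standard_normal((len(modules), n_samples))
    z = rng.standard_normal((len(genes), n_samples))
    a = np.sqrt(r_target)
    b = np.sqrt(1.0 - r_target)
    for mod_idx, mod in enumerate(modules):
        for g in mod:
            z[index[g]] = a * latent[mod_idx] + b * z[index[g]]
    values = np.maximum(0.0, 50.0 + 10.0 * z)

    import pandas as pd

    df = pd.DataFrame(
        values, index=genes,
        columns=[f"sample-{j + 1:02d}" for j in range(n_samples)],
    )
    truths = [
        TruthRecord(
            kind="coexpression_pair",
            ids={"gene_a": mod[i], "gene_b": mod[j]},
            params={"module": mod_idx, "r_target": r_target},
            seed=seed,
        )
        for mod_idx, mod in enumerate(modules)
        for i in range(len(mod))
        for j in range(i + 1, len(mod))
    ]
    return ExpressionMatrix(df), truths


def gen_go_annotations(
    genes: Sequence[str],
    n_terms: int,
    module_term_map: Sequence[tuple[Sequence[str], str]] = (),
    background_rate: float = 0.05,
    seed: int = 0,
) -> tuple["GOAnnotation", list[TruthRecord]]:
    """Annotation where each module's genes all carry its designated term and
    background terms are sprinkled at a low uniform rate."""
    from .coexpression import GOAnnotation

    terms_used = [t for _m, t in module_term_map]
    if len(terms_used) != len(set(terms_used)):
        raise ValidationError("term collision across modules")
    rng = np.random.default_rng(seed)
    background_terms = [f"GO:BG{i + 1:04d}" for i in range(n_terms)]
    ann = GOAnnotation()
    for gene in genes:
        ann.gene_terms.setdefault(gene, set())
        for term in background_terms:
            if rng.random() < background_rate:
                ann.gene_terms[gene].add(term)
    truths = []
    for members, term in module_term_map:
        for gene in members:
            ann.gene_terms.setdefault(gene, set()).add(term)
        truths.append(
            TruthRecord(
                kind="enriched_term",
                ids={"term": term},
                params={"members": list(members)},
                seed=seed,
            )
        )
    return ann, truths


# ---------------------------------------------------------------------------
# Ortholog windows
# ---------------------------------------------------------------------------

def gen_ortholog_windows(
    window: str,
    n_species: int,
    site_offsets: tuple[int, int],
    site_divergence: float = 0.05,
    flank_divergence: float = 0.40,
    seed: int = 0,
) -> tuple[list[str], TruthRecord]:
    """Species copies of a window mutated at different site vs flank rates.

    Substitutions are uniform over the three other bases; no indels, so the
    copies stay column-aligned with the reference.
    """
    lo, hi = site_offsets
    if not (0 <= site_divergence <= 1 and 0 <= flank_divergence <= 1):
        raise ValidationError("divergences must lie in [0, 1]")
    if not 1 <= lo <= hi <= len(window):
        raise ValidationError("site offsets outside the window")
    rng = np.random.default_rng(seed)
    copies = []
    for _s in range(n_species):
        chars = list(window)
        for i in range(len(chars)):
            rate = site_divergence if lo <= i + 1 <= hi else flank_divergence
            if rng.random() < rate:
                chars[i] = str(rng.choice([b for b in "ACGU" if b != chars[i]]))
        copies.append("".join(chars))
    truth = TruthRecord(
        kind="conserved_site",
        ids={},
        params={
            "site_offsets": [lo, hi],
            "site_divergence": site_divergence,
            "flank_divergence": flank_divergence,
            "n_species": n_species,
        },
        seed=seed,
    )
    return copies, truth
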