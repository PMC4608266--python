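"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as straightforward re-derivations —
quadratic scans, literal re-counts, exact tail summation — and must stay
independent of the implementation paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

from lincmir.duplex import PairState


# --- interval overlap ------------------------------------------------------

def overlaps_bruteforce(linc_iv, blockers) -> bool:
    """All-pairs >=1 bp overlap test under 1-based inclusive coordinates."""
    for iv in blockers:
        if iv.chrom != linc_iv.chrom:
            continue
        shared = min(linc_iv.end, iv.end) - max(linc_iv.start, iv.start) + 1
        if shared >= 1:
            return True
    return False


# --- rule engine -----------------------------------------------------------

def rule_verdict_bruteforce(columns) -> str:
    """Literal re-statement of the target/decoy rules over alignment columns.

    Returns 'target', 'decoy' or 'none'.  Coded independently of the
    classifier: defects are listed with their assigned miRNA positions first,
    then each clause is checked directly against that list.
    """
    assigned = []  # (position, state) per defect column
    last_mirna_pos = 0
    for col in columns:
        if col.mirna_pos is not None:
            last_mirna_pos = col.mirna_pos
        if col.state in (PairState.WC, PairState.GU):
            continue
        if col.state == PairState.BULGE_TARGET:
            assigned.append((max(1, last_mirna_pos), col.state))
        else:
            assigned.append((col.mirna_pos, col.state))

    central = [a for a in assigned if 9 <= a[0] <= 12]
    noncentral = [a for a in assigned if not 9 <= a[0] <= 12]
    outer = [a for a in noncentral if a[0] == 1 or a[0] >= 13]

    # longest run of consecutive MISMATCH columns
    longest = current = 0
    for col in columns:
        if col.state == PairState.MISMATCH:
            current += 1
            longest = max(longest, current)
        else:
            current = 0

    if len(central) <= 1 and len(noncentral) <= 4 and longest <= 1:
        return "target"

    seed_ok = True
    for col in columns:
        if col.mirna_pos is not None and 2 <= col.mirna_pos <= 8:
            if col.state not in (PairState.WC, PairState.GU):
                seed_ok = False
    # a transcript bulge between miRNA positions i and i+1 with i in 1..8
    # touches the seed block
    lastpos = 0
    for col in columns:
        if col.mirna_pos is not None:
            lastpos = col.mirna_pos
        elif col.state == PairState.BULGE_TARGET and 1 <= lastpos <= 8:
            seed_ok = False

    if 2 <= len(central) <= 5 and seed_ok and len(outer) <= 4:
        return "decoy"
    return "none"


# --- degradome categories --------------------------------------------------

def category_bruteforce(abundance: dict[int, int], position: int):
    """Literal category definition over an abundance map."""
    a = abundance.get(position, 0)
    if a == 0:
        return None
    if a == 1:
        return 4
    values = sorted(abundance.values())
    peak = values[-1]
    mid = len(values) // 2
    if len(values) % 2:
        med = values[mid]
    else:
        med = (values[mid - 1] + values[mid]) / 2
    if a == peak:
        return 0 if values.count(peak) == 1 else 1
    if a > med:
        return 2
    return 3


# --- 5'-end mapping --------------------------------------------------------

def map_ends_bruteforce(unique_reads: dict[str, int], sequence: str) -> dict[int, int]:
    """Quadratic all-positions substring scan."""
    out: dict[int, int] = {}
    for pos in range(1, len(sequence) + 1):
        for read, count in unique_reads.items():
            if sequence[pos - 1 : pos - 1 + len(read)] == read and \
                    pos - 1 + len(read) <= len(sequence):
                out[pos] = out.get(pos, 0) + count
    return out


# --- statistics ------------------------------------------------------------

def fisher_z_pvalue_bruteforce(r: float, n: int) -> float:
    """p = 2*(1 - Phi(|z|)) evaluated through erfc, independent of scipy."""
    r = max(-(1 - 1e-15), min(1 - 1e-15, r))
    z = 0.5 * math.log((1 + r) / (1 - r)) * math.sqrt(n - 3)
    return math.erfc(abs(z) / math.sqrt(2.0))


def hypergeom_tail_bruteforce(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k) by term-by-term rational summation."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


# --- alignment -------------------------------------------------------------

def best_ungapped_alignment(mirna_seq: str, transcript_seq: str,
                            match=1.0, gu=0.5, mismatch=-1.0):
    """Best gapless antiparallel placement of the whole miRNA on a transcript.

    Returns (score, site_start_1based, states in miRNA order 1..L).
    """
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "U"), ("U", "G")}
    L = len(mirna_seq)
    best = (-math.inf, None, None)
    for start in range(0, len(transcript_seq) - L + 1):
        window = transcript_seq[start : start + L]
        score = 0.0
        states = []
        for p in range(1, L + 1):
            mb = mirna_seq[p - 1]
            tb = window[L - p]  # antiparallel: miRNA pos 1 pairs window 3' end
            if (mb, tb) in wc:
                score += match
                states.append("WC")
            elif (mb, tb) in wob:
                score += gu
                states.append("GU")
            else:
                score += mismatch
                states.append("MISMATCH")
        if score > best[0]:
            best = (score, start + 1, states)
    return best


# --- union-find ------------------------------------------------------------

def connected_components_bruteforce(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))


# --- homology search -------------------------------------------------------

def seeded_segments_bruteforce(query: str, subject: str, seed_len=7,
                               match=1.0, mismatch=-2.0, xdrop=10.0):
    """Per-diagonal re-derivation of seeded X-drop segments (one strand).

    For every exact seed, extends right then left exactly as defined and
    yields (qs, qe, ss, se, score) 0-based half-open segments.
    """
    out = set()
    for i in range(len(query) - seed_len + 1):
        word = query[i : i + seed_len]
        for j in range(len(subject) - seed_len + 1):
            if subject[j : j + seed_len] != word:
                continue
            score = float(seed_len) * match
            best, ext_r = score, 0
            step = 0
            while i + seed_len + step < len(query) and j + seed_len + step < len(subject):
                score += match if query[i + seed_len + step] == subject[j + seed_len + step] else mismatch
                step += 1
                if score > best:
                    best, ext_r = score, step
                if best - score > xdrop:
                    break
            score = best
            best_l = 0
            run = score
            step = 0
            while i - 1 - step >= 0 and j - 1 - step >= 0:
                run += match if query[i - 1 - step] == subject[j - 1 - step] else mismatch
                step += 1
                if run > score:
                    score, best_l = run, step
                if score - run > xdrop:
                    break
            out.add((i - best_l, i + seed_len + ext_r,
                     j - best_l, j + seed_len + ext_r, score))
    return out
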