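"""Co-expression network and GO-based function transfer for lincRNAs.

Pipeline: keep the top-variance genes, compute Pearson correlations with
Fisher z-transform p-values for every lincRNA-mRNA pair, Bonferroni-adjust,
retain pairs passing both the adjusted-alpha and the top/bottom correlation
tails, and annotate lincRNAs by one-sided Fisher-exact GO over-representation
of their co-expressed (targets) or miRNA-shared (decoys, ceRNA rule) mRNAs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .network import RegulatoryNetwork
from .seq_io import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

_R_CLAMP = 1.0 - 1e-15


@dataclass(frozen=True)
class CoexpressionEdge:
    lincrna_id: str
    mrna_id: str
    pcc: float
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if abs(self.pcc) > 1:
            raise ValidationError("|pcc| must be <= 1")
        if not 0 <= self.p_raw <= self.p_adj <= 1:
            raise ValidationError("need 0 <= p_raw <= p_adj <= 1")


@dataclass
class GOAnnotation:
    gene_terms: dict[str, set[str]] = field(default_factory=dict)

    @property
    def universe(self) -> set[str]:
        terms: set[str] = set()
        for ts in self.gene_terms.values():
            terms |= ts
        return terms

    @property
    def genes(self) -> set[str]:
        return set(self.gene_terms)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    query_hits: int      # k
    query_size: int      # n
    background_hits: int  # K
    background_size: int  # N
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.query_hits > min(self.query_size, self.background_hits):
            raise ValidationError("k must be <= min(n, K)")


# ---------------------------------------------------------------------------
# Filtering and statistics
# ---------------------------------------------------------------------------

def variance_filter(
    matrix: ExpressionMatrix, keep_fraction: float = 0.75
) -> ExpressionMatrix:
    """Keep the ceil(keep_fraction * n_genes) genes with the largest sample
    variance; ties are broken by input order."""
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must lie in (0, 1]")
    if len(matrix.samples) < 2:
        raise ValidationError("need at least 2 samples")
    values = matrix.values.to_numpy()
    variances = values.var(axis=1, ddof=1)
    n_keep = math.ceil(keep_fraction * len(matrix.genes))
    order = np.argsort(-variances, kind="stable")[:n_keep]
    keep_idx = sorted(order)  # preserve input order among the kept genes
    return ExpressionMatrix(matrix.values.iloc[keep_idx])


def correlation_pvalue(x, y) -> tuple[float, float]:
    """Pearson r and its Fisher z-transform (asymptotic normal) p-value.

    p = 2 * (1 - Phi(|z|)) with z = atanh(r) * sqrt(n - 3); r is clamped to
    +/-(1 - 1e-15) before the transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    z = math.atanh(max(-_R_CLAMP, min(_R_CLAMP, r))) * math.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return r, float(p)


def bonferroni_adjust(p_values, m: int | None = None):
    """min(1, m * p) per value; m defaults to the number of values given."""
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = arr.size
    adj = np.minimum(1.0, m * arr)
    if np.isscalar(p_values) or np.asarray(p_values).ndim == 0:
        return float(adj[0])
    return adj


def select_coexpression_edges(
    matrix: ExpressionMatrix,
    lincrna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    alpha: float = 0.05,
    tail_fraction: float = 0.05,
) -> list[CoexpressionEdge]:
    """Correlate every lincRNA-mRNA pair; keep pairs with Bonferroni-adjusted
    p < alpha AND a correlation in the top or bottom ``tail_fraction`` of the
    computed pair distribution.

    The Bonferroni multiplier is the number of pairs computed.
    """
    lincrna_ids = list(lincrna_ids)
    mrna_ids = list(mrna_ids)
    if not lincrna_ids or not mrna_ids:
        raise ValidationError("empty id set")
    missing = (set(lincrna_ids) | set(mrna_ids)) - set(matrix.genes)
    if missing:
        raise ValidationError(f"ids absent from matrix: {sorted(missing)[:5]}")
    overlap = set(lincrna_ids) & set(mrna_ids)
    if overlap:
        raise ValidationError(f"id sets must be disjoint: {sorted(overlap)[:5]}")

    n = len(matrix.samples)
    if n < 4:
        raise ValidationError("need at least 4 samples")
    lx = matrix.values.loc[list(lincrna_ids)].to_numpy()
    mx = matrix.values.loc[list(mrna_ids)].to_numpy()

    def standardize(block: np.ndarray, ids: Sequence[str]) -> np.ndarray:
        centered = block - block.mean(axis=1, keepdims=True)
        norm = np.sqrt((centered**2).sum(axis=1, keepdims=True))
        if (norm == 0).any():
            bad = [g for g, nn in zip(ids, norm[:, 0]) if nn == 0]
            raise ValidationError(f"zero-variance gene(s): {bad[:5]}")
        return centered / norm

    rmat = standardize(lx, lincrna_ids) @ standardize(mx, mrna_ids).T
    rmat = np.clip(rmat, -1.0, 1.0)
    z = np.arctanh(np.clip(rmat, -_R_CLAMP, _R_CLAMP)) * math.sqrt(n - 3)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    m_tests = rmat.size
    p_adj = np.minimum(1.0, m_tests * p_raw)

    flat = rmat.ravel()
    hi = np.quantile(flat, 1.0 - tail_fraction)
    lo = np.quantile(flat, tail_fraction)
    in_tail = (rmat >= hi) | (rmat <= lo)
    keep = (p_adj < alpha) & in_tail

    edges = [
        CoexpressionEdge(
            lincrna_id=lincrna_ids[i],
            mrna_id=mrna_ids[j],
            pcc=float(rmat[i, j]),
            p_raw=float(p_raw[i, j]),
            p_adj=float(p_adj[i, j]),
        )
        for i, j in zip(*np.nonzero(keep))
    ]
    edges.sort(key=lambda e: (e.p_adj, e.lincrna_id, e.mrna_id))
    return edges


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def fisher_overrepresentation_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher exact (hypergeometric upper tail) P(X >= k)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(f"invalid 2x2 table k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def go_enrichment(
    query_genes: Sequence[str],
    annotation: GOAnnotation,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of each term with >= 1 query hit, Bonferroni over
    the number of terms tested; results with p_adj < alpha, sorted by p_adj."""
    query = set(query_genes)
    if not query:
        raise ValidationError("empty query")
    background = annotation.genes
    stray = query - background
    if stray:
        raise ValidationError(
            f"query genes missing from annotation: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(query)
    term_background: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for gene, terms in annotation.gene_terms.items():
        for term in terms:
            term_background[term] = term_background.get(term, 0) + 1
            if gene in query:
                term_hits[term] = term_hits.get(term, 0) + 1
    tested = sorted(term_hits)
    m = len(tested)
    results = []
    for term in tested:
        k = term_hits[term]
        K = term_background[term]
        p = fisher_overrepresentation_pvalue(k, n, K, N)
        results.append(
            EnrichmentResult(
                term=term, query_hits=k, query_size=n,
                background_hits=K, background_size=N,
                p_raw=p, p_adj=min(1.0, m * p),
            )
        )
    results = [r for r in results if r.p_adj < alpha]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return results


# ---------------------------------------------------------------------------
# Function transfer
# ---------------------------------------------------------------------------

def annotate_lincrna_targets(
    lincrna_id: str,
    edges: Sequence[CoexpressionEdge],
    annotation: GOAnnotation,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """GO enrichment of the mRNAs co-expressed with one lincRNA target."""
    partners = sorted(
        {e.mrna_id for e in edges if e.lincrna_id == lincrna_id}
    )
    partners = [p for p in partners if p in annotation.gene_terms]
    if not partners:
        log.warning("lincRNA %s has no annotated co-expression partners", lincrna_id)
        return []
    return go_enrichment(partners, annotation, alpha)


def annotate_lincrna_decoys(
    lincrna_id: str,
    network: RegulatoryNetwork,
    annotation: GOAnnotation,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """ceRNA-rule GO transfer: enrich the mRNAs that are *targets* of any
    miRNA holding a *decoy* edge to this lincRNA."""
    info = network.nodes.get(lincrna_id)
    if info is None or "decoy" not in info.roles:
        raise ValidationError(f"{lincrna_id!r} is not a decoy in the network")
    partners: set[str] = set()
    for mirna in network.mirnas_with_decoy(lincrna_id):
        partners |= network.targets_of(mirna, kind="mRNA")
    partners = sorted(p for p in partners if p in annotation.gene_terms)
    if not partners:
        log.warning("decoy %s shares no annotated mRNA targets", lincrna_id)
        return []
    return go_enrichment(partners, annotation, alpha)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_go_annotation(path) -> GOAnnotation:
    """Two-column TSV: gene id, GO term (one term per line)."""
    ann = GOAnnotation()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 2 columns"
                )
            gene, term = fields
            ann.gene_terms.setdefault(gene, set()).add(term)
    return ann


def write_go_annotation(ann: GOAnnotation, path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(ann.gene_terms):
            for term in sorted(ann.gene_terms[gene]):
                handle.write(f"{gene}\t{term}\n")


def write_edge_table(edges: Sequence[CoexpressionEdge], path) -> None:
    with open(path, "w") as handle:
        handle.write("lincrna_id\tmrna_id\tpcc\tp_raw\tp_adj\n")
        for e in edges:
            handle.write(
                f"{e.lincrna_id}\t{e.mrna_id}\t{e.pcc:.15g}\t"
                f"{e.p_raw:.6g}\t{e.p_adj:.6g}\n"
            )


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "term\tquery_hits\tquery_size\tbackground_hits\tbackground_size\t"
            "p_raw\tp_adj\n"
        )
        for r in results:
            handle.write(
                f"{r.term}\t{r.query_hits}\t{r.query_size}\t{r.background_hits}\t"
                f"{r.background_size}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\n"
            )
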