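import math

import numpy as np
import pandas as pd
import pytest

from lincmir.classify import InteractionCall, Verdict, region_diagnostics
from lincmir.coexpression import (
    GOAnnotation,
    annotate_lincrna_decoys,
    annotate_lincrna_targets,
    bonferroni_adjust,
    correlation_pvalue,
    fisher_overrepresentation_pvalue,
    go_enrichment,
    read_go_annotation,
    select_coexpression_edges,
    variance_filter,
    write_go_annotation,
)
from lincmir.network import build_network
from lincmir.seq_io import ExpressionMatrix, ValidationError
from lincmir import synthetic as syn

from conftest import make_alignment
from oracles import fisher_z_pvalue_bruteforce, hypergeom_tail_bruteforce


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestVarianceFilter:
    def test_keeps_ceil_of_fraction(self):
        rows = [
            [10, 10 + i, 10 - i, 10 + 2 * i, 10 - 2 * i] for i in (1, 2, 3, 4)
        ]
        m = variance_filter(_matrix(rows))
        assert m.genes == ["g1", "g2", "g3"]  # variances 1 < 2 < 3 < 4-ish

    def test_all_constant_ties_keep_first(self):
        m = variance_filter(_matrix(np.ones((4, 5))))
        assert m.genes == ["g0", "g1", "g2"]

    def test_matches_sort_and_slice_oracle(self, rng):
        values = rng.random((30, 8)) * 100
        m = variance_filter(_matrix(values), keep_fraction=0.6)
        variances = values.var(axis=1, ddof=1)
        n_keep = math.ceil(0.6 * 30)
        order = sorted(range(30), key=lambda i: (-variances[i], i))[:n_keep]
        assert m.genes == [f"g{i}" for i in sorted(order)]

    def test_bad_fraction(self):
        with pytest.raises(ValidationError):
            variance_filter(_matrix(np.ones((3, 4))), keep_fraction=0)


class TestCorrelationPvalue:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        r, p = correlation_pvalue(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-200

    def test_zero_correlation_gives_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, p = correlation_pvalue(x, y)
        assert r == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_known_value_r_half_n30(self):
        # z = atanh(0.5) * sqrt(27) ~ 2.854 -> p ~ 4.3e-3
        z = math.atanh(0.5) * math.sqrt(27)
        expected = math.erfc(z / math.sqrt(2))
        assert expected == pytest.approx(4.3e-3, rel=0.02)
        x = np.array([0.0, 1, 2, 3] * 10)
        rng = np.random.default_rng(0)
        # calibrate a vector pair to near r=0.5, then compare to the oracle
        y = 0.5 * x + rng.standard_normal(40)
        r, p = correlation_pvalue(x, y)
        assert p == pytest.approx(fisher_z_pvalue_bruteforce(r, 40), rel=1e-9)

    def test_grid_against_oracle(self, rng):
        for n in (4, 8, 15, 30, 100):
            for _ in range(10):
                x = rng.standard_normal(n)
                y = rng.standard_normal(n) + rng.random() * x
                r, p = correlation_pvalue(x, y)
                assert p == pytest.approx(
                    fisher_z_pvalue_bruteforce(r, n), rel=1e-9, abs=1e-300
                )

    def test_symmetry_and_monotonicity(self):
        n = 20
        rs = [0.1, 0.3, 0.5, 0.7, 0.9]
        ps = [fisher_z_pvalue_bruteforce(r, n) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        for r in rs:
            assert fisher_z_pvalue_bruteforce(r, n) == pytest.approx(
                fisher_z_pvalue_bruteforce(-r, n)
            )

    def test_validation(self):
        with pytest.raises(ValidationError):
            correlation_pvalue([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValidationError):
            correlation_pvalue([1, 1, 1, 1], [1, 2, 3, 4])


class TestBonferroni:
    def test_scalar(self):
        assert bonferroni_adjust(0.02, m=10) == pytest.approx(0.2)

    def test_cap_at_one(self):
        assert bonferroni_adjust(0.5, m=10) == 1.0

    def test_vector_equals_scalar(self, rng):
        ps = rng.random(20)
        vec = bonferroni_adjust(ps, m=20)
        for p, a in zip(ps, vec):
            assert a == bonferroni_adjust(float(p), m=20)

    def test_never_decreases(self, rng):
        ps = rng.random(50)
        assert (bonferroni_adjust(ps) >= ps).all()

    def test_bad_p(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([0.5, 1.2])


class TestSelectEdges:
    def test_planted_pair_retained(self):
        matrix, _ = syn.gen_expression_with_modules(
            100, n_samples=30,
            modules=[["linc-X", "mrna-Y"]],
            r_target=0.95, seed=4,
        )
        lincs = ["linc-X"]
        mrnas = [g for g in matrix.genes if g not in ("linc-X",)]
        edges = select_coexpression_edges(matrix, lincs, mrnas)
        assert any(e.mrna_id == "mrna-Y" for e in edges)

    def test_noise_only_typically_empty(self):
        matrix, _ = syn.gen_expression_with_modules(
            30, n_samples=20, modules=[], seed=8
        )
        edges = select_coexpression_edges(
            matrix, matrix.genes[:5], matrix.genes[5:25]
        )
        assert edges == []

    def test_degenerate_thresholds_keep_all(self):
        matrix, _ = syn.gen_expression_with_modules(
            12, n_samples=10, modules=[], seed=2
        )
        edges = select_coexpression_edges(
            matrix, matrix.genes[:3], matrix.genes[3:],
            alpha=1.0000001, tail_fraction=1.0,
        )
        assert len(edges) == 3 * 9

    def test_empty_ids_error(self):
        matrix, _ = syn.gen_expression_with_modules(6, n_samples=8, seed=1)
        with pytest.raises(ValidationError):
            select_coexpression_edges(matrix, [], matrix.genes)

    def test_edge_invariants(self):
        matrix, _ = syn.gen_expression_with_modules(
            40, n_samples=25,
            modules=[["linc-A", "m-1"], ["linc-B", "m-2"]],
            seed=6,
        )
        edges = select_coexpression_edges(
            matrix, ["linc-A", "linc-B"],
            [g for g in matrix.genes if not g.startswith("linc-")],
            alpha=1.0, tail_fraction=0.5,
        )
        for e in edges:
            assert abs(e.pcc) <= 1
            assert 0 <= e.p_raw <= e.p_adj <= 1


class TestGoEnrichment:
    def _annotation(self):
        ann = GOAnnotation()
        for i in range(100):
            ann.gene_terms[f"g{i}"] = {"GO:A"} if i < 10 else {"GO:B"}
        return ann

    def test_query_equals_background_p_one(self):
        ann = self._annotation()
        results = go_enrichment(sorted(ann.genes), ann, alpha=1.1)
        assert results
        for r in results:
            assert r.p_raw == pytest.approx(1.0)

    def test_worked_table(self):
        # background 100, term on 10; query of 10 with 5 hits
        p = fisher_overrepresentation_pvalue(5, 10, 10, 100)
        assert p == pytest.approx(hypergeom_tail_bruteforce(5, 10, 10, 100),
                                  rel=1e-12)

    def test_tables_match_bruteforce_sample(self, rng):
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k_lo = max(0, n + K - N)
            k_hi = min(n, K)
            k = int(rng.integers(k_lo, k_hi + 1))
            assert fisher_overrepresentation_pvalue(
                k, n, K, N
            ) == pytest.approx(hypergeom_tail_bruteforce(k, n, K, N), rel=1e-10)

    def test_planted_module_top(self):
        ann, truths = syn.gen_go_annotations(
            [f"g{i}" for i in range(200)], n_terms=8,
            module_term_map=[([f"g{i}" for i in range(10)], "GO:PLANT")],
            seed=5,
        )
        results = go_enrichment([f"g{i}" for i in range(10)], ann)
        assert results[0].term == "GO:PLANT"

    def test_empty_query(self):
        with pytest.raises(ValidationError):
            go_enrichment([], self._annotation())

    def test_roundtrip_annotation_io(self, tmp_path):
        ann, _ = syn.gen_go_annotations(
            [f"g{i}" for i in range(20)], n_terms=4, seed=9
        )
        p = tmp_path / "go.tsv"
        write_go_annotation(ann, p)
        back = read_go_annotation(p)
        assert back.gene_terms == {
            g: t for g, t in ann.gene_terms.items() if t
        }


class TestFunctionTransfer:
    def _setup(self):
        genes = [f"m-{i}" for i in range(30)]
        ann, _ = syn.gen_go_annotations(
            genes, n_terms=5,
            module_term_map=[(["m-0", "m-1", "m-2"], "GO:FN")],
            seed=3,
        )
        return genes, ann

    def test_targets_route(self):
        _genes, ann = self._setup()
        from lincmir.coexpression import CoexpressionEdge

        edges = [
            CoexpressionEdge("linc-1", f"m-{i}", 0.9, 1e-8, 1e-6)
            for i in range(3)
        ]
        results = annotate_lincrna_targets("linc-1", edges, ann)
        assert results[0].term == "GO:FN"

    def test_targets_route_no_edges(self):
        _genes, ann = self._setup()
        assert annotate_lincrna_targets("linc-1", [], ann) == []

    def test_targets_order_invariant(self):
        _genes, ann = self._setup()
        from lincmir.coexpression import CoexpressionEdge

        edges = [
            CoexpressionEdge("linc-1", f"m-{i}", 0.9, 1e-8, 1e-6)
            for i in range(3)
        ]
        a = annotate_lincrna_targets("linc-1", edges, ann)
        b = annotate_lincrna_targets("linc-1", edges[::-1], ann)
        assert a == b

    def _decoy_network(self):
        def call(m, t, verdict):
            aln = make_alignment(21, mirna_id=m, transcript_id=t)
            return InteractionCall(verdict, region_diagnostics(aln), aln)

        calls = [
            call("miR-1", "linc-D", Verdict.DECOY),
            call("miR-1", "m-0", Verdict.TARGET),
            call("miR-1", "m-1", Verdict.TARGET),
            call("miR-1", "m-2", Verdict.TARGET),
            call("miR-2", "linc-D", Verdict.DECOY),
            call("miR-2", "m-2", Verdict.TARGET),
            call("miR-2", "m-3", Verdict.TARGET),
        ]
        biotypes = {f"m-{i}": "mRNA" for i in range(30)}
        biotypes["linc-D"] = "lincRNA"
        return build_network(calls, biotypes)

    def test_cerna_partner_union(self):
        _genes, ann = self._setup()
        net = self._decoy_network()
        results = annotate_lincrna_decoys("linc-D", net, ann)
        # partners are m-0..m-3 deduplicated; planted term must surface
        assert results[0].term == "GO:FN"

    def test_cerna_requires_decoy_role(self):
        _genes, ann = self._setup()
        net = self._decoy_network()
        with pytest.raises(ValidationError):
            annotate_lincrna_decoys("m-0", net, ann)

    def test_cerna_planted_module_recovered(self):
        genes, ann = self._setup()
        net = self._decoy_network()
        results = annotate_lincrna_decoys("linc-D", net, ann)
        assert any(r.term == "GO:FN" for r in results)
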