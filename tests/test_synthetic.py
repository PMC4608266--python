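import numpy as np
import pytest

from lincmir.classify import Verdict, classify_interaction
from lincmir.duplex import ScanParams, scan_candidate_sites
from lincmir.seq_io import Transcript, ValidationError
from lincmir import synthetic as syn


class TestGenMirnas:
    def test_deterministic(self):
        assert syn.gen_mirnas(10, seed=3) == syn.gen_mirnas(10, seed=3)

    def test_distinct_ids_and_sequences(self):
        mirnas = syn.gen_mirnas(10, seed=1)
        assert len({m.id for m in mirnas}) == 10
        assert len({m.sequence for m in mirnas}) == 10

    def test_length_bounds_over_many_draws(self):
        mirnas = syn.gen_mirnas(1000, length_range=(19, 23), seed=2)
        lengths = {len(m) for m in mirnas}
        assert lengths <= set(range(19, 24))
        assert len(lengths) > 1

    def test_bad_range(self):
        with pytest.raises(ValidationError):
            syn.gen_mirnas(5, length_range=(10, 12), seed=0)


class TestImplantSite:
    def test_zero_defects_yields_target(self, rng):
        mi = syn.gen_mirnas(1, seed=1)[0]
        bg = Transcript("tx", syn.random_rna(rng, 150))
        tx, truth = syn.implant_site(bg, mi, [], 40, seed=1)
        assert truth.kind == "target_site"
        hits = scan_candidate_sites(mi, tx)
        assert classify_interaction(hits[0]).verdict is Verdict.TARGET

    def test_central_mismatches_yield_decoy(self, rng):
        mi = syn.gen_mirnas(1, seed=1)[0]
        bg = Transcript("tx", syn.random_rna(rng, 150))
        tx, truth = syn.implant_site(
            bg, mi, [(10, "MISMATCH"), (12, "MISMATCH")], 40, seed=1
        )
        assert truth.kind == "decoy_site"

    def test_conflicting_defects_error(self, rng):
        mi = syn.gen_mirnas(1, seed=1)[0]
        bg = Transcript("tx", syn.random_rna(rng, 150))
        with pytest.raises(ValidationError, match="conflict"):
            syn.implant_site(
                bg, mi, [(10, "MISMATCH"), (10, "BULGE_MIRNA")], 40
            )

    def test_site_must_fit(self, rng):
        mi = syn.gen_mirnas(1, seed=1)[0]
        bg = Transcript("tx", syn.random_rna(rng, 30))
        with pytest.raises(ValidationError):
            syn.implant_site(bg, mi, [], 20)

    def test_deterministic(self, rng):
        mi = syn.gen_mirnas(1, seed=1)[0]
        bg = Transcript("tx", syn.random_rna(rng, 150))
        a, _ = syn.implant_site(bg, mi, [(9, "BULGE_TARGET")], 40, seed=5)
        b, _ = syn.implant_site(bg, mi, [(9, "BULGE_TARGET")], 40, seed=5)
        assert a.sequence == b.sequence

    def test_random_conformant_specs_recovered_end_to_end(self):
        # smaller sibling of the acceptance-scale run
        rng = np.random.default_rng(77)
        mirnas = syn.gen_mirnas(10, seed=6)
        for _ in range(100):
            mi = mirnas[rng.integers(0, len(mirnas))]
            spec = syn.random_decoy_spec(rng, mi.sequence)
            bg = Transcript("tx", syn.random_rna(rng, 200))
            tx, truth = syn.implant_site(
                bg, mi, spec, 60, seed=int(rng.integers(2**31))
            )
            assert truth.params["verdict"] == "decoy"
            hits = scan_candidate_sites(
                mi, tx, ScanParams(mfe_ratio_cutoff=0.35)
            )
            exact = [
                h for h in hits
                if (h.site_start, h.site_end)
                == (truth.params["site_start"], truth.params["site_end"])
            ]
            assert exact, spec
            assert classify_interaction(exact[0]).verdict is Verdict.DECOY


class TestGenTranscriptome:
    def test_deterministic(self):
        mirnas = syn.gen_mirnas(3, seed=1)
        plan = [(0, 0, []), (1, 1, [(10, "MISMATCH"), (12, "MISMATCH")])]
        a, ta = syn.gen_transcriptome(mirnas, 2, 2, plan, seed=4)
        b, tb = syn.gen_transcriptome(mirnas, 2, 2, plan, seed=4)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        assert [t.to_json() for t in ta] == [t.to_json() for t in tb]

    def test_all_planned_sites_in_truths(self):
        mirnas = syn.gen_mirnas(4, seed=2)
        plan = [(i % 4, i % 4, []) for i in range(8)]
        _txs, truths = syn.gen_transcriptome(mirnas, 2, 2, plan, seed=3)
        assert len(truths) == 8

    def test_density_error(self):
        mirnas = syn.gen_mirnas(1, seed=1)
        plan = [(0, 0, [])] * 50
        with pytest.raises(ValidationError, match="density|capacity"):
            syn.gen_transcriptome(mirnas, 1, 0, plan, mean_len=150, seed=1)

    def test_background_has_no_accidental_site(self):
        mirnas = syn.gen_mirnas(5, seed=8)
        txs, _ = syn.gen_transcriptome(mirnas, 3, 3, [], mean_len=400, seed=9)
        for tx in txs:
            for mi in mirnas:
                assert scan_candidate_sites(mi, tx) == []

    def test_biotypes_split(self):
        mirnas = syn.gen_mirnas(1, seed=1)
        txs, _ = syn.gen_transcriptome(mirnas, 3, 2, [], seed=1)
        assert [t.biotype for t in txs] == ["lincRNA"] * 3 + ["mRNA"] * 2


class TestGenDegradome:
    def _data(self):
        mirnas = syn.gen_mirnas(3, seed=1)
        plan = [(i, i, []) for i in range(3)]
        txs, truths = syn.gen_transcriptome(mirnas, 3, 0, plan, seed=2)
        return txs, truths

    def test_peak_abundance_at_planted_positions(self):
        txs, truths = self._data()
        lib = syn.gen_degradome(truths, txs, peak_reads=10, seed=3)
        from lincmir.degradome import map_five_prime_ends

        for truth in truths:
            tx = next(t for t in txs if t.id == truth.ids["transcript"])
            profile = map_five_prime_ends(lib, tx)
            assert profile.at(truth.params["cleavage_position"]) >= 10

    def test_reads_are_exact_substrings(self):
        txs, truths = self._data()
        lib = syn.gen_degradome(truths, txs, seed=3)
        joined = [t.sequence for t in txs]
        for read in lib.unique_reads:
            assert any(read in s for s in joined)

    def test_deterministic(self):
        txs, truths = self._data()
        a = syn.gen_degradome(truths, txs, seed=3)
        b = syn.gen_degradome(truths, txs, seed=3)
        assert a.unique_reads == b.unique_reads


class TestGenExpression:
    def test_within_module_correlation_near_target(self):
        modules = [[f"mod-{m}-{g}" for g in range(5)] for m in range(4)]
        matrix, _ = syn.gen_expression_with_modules(
            200, n_samples=30, modules=modules, r_target=0.9, seed=5
        )
        rs = []
        for mod in modules:
            for i in range(len(mod)):
                for j in range(i + 1, len(mod)):
                    r = np.corrcoef(matrix.row(mod[i]), matrix.row(mod[j]))[0, 1]
                    rs.append(r)
        assert abs(np.mean(rs) - 0.9) < 0.1

    def test_cross_module_correlation_near_zero(self):
        modules = [["a1", "a2"], ["b1", "b2"]]
        matrix, _ = syn.gen_expression_with_modules(
            50, n_samples=30, modules=modules, seed=6
        )
        r = np.corrcoef(matrix.row("a1"), matrix.row("b1"))[0, 1]
        assert abs(r) < 0.5

    def test_non_negative(self):
        matrix, _ = syn.gen_expression_with_modules(50, n_samples=10, seed=7)
        assert (matrix.values.to_numpy() >= 0).all()

    def test_deterministic(self):
        a, _ = syn.gen_expression_with_modules(20, n_samples=8, seed=9)
        b, _ = syn.gen_expression_with_modules(20, n_samples=8, seed=9)
        assert a.values.equals(b.values)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            syn.gen_expression_with_modules(10, n_samples=3, seed=1)

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValidationError):
            syn.gen_expression_with_modules(
                10, modules=[["x", "y"], ["y", "z"]], seed=1
            )


class TestGenGoAnnotations:
    def test_module_genes_carry_term(self):
        genes = [f"g{i}" for i in range(50)]
        ann, truths = syn.gen_go_annotations(
            genes, n_terms=5,
            module_term_map=[(genes[:8], "GO:X")], seed=2,
        )
        for g in genes[:8]:
            assert "GO:X" in ann.gene_terms[g]
        assert truths[0].ids["term"] == "GO:X"

    def test_background_rate_bounded(self):
        genes = [f"g{i}" for i in range(500)]
        ann, _ = syn.gen_go_annotations(
            genes, n_terms=4, background_rate=0.05, seed=3
        )
        total = sum(
            1 for ts in ann.gene_terms.values() for t in ts
            if t.startswith("GO:BG")
        )
        rate = total / (500 * 4)
        assert 0.02 < rate < 0.09

    def test_term_collision_error(self):
        with pytest.raises(ValidationError):
            syn.gen_go_annotations(
                ["a", "b"], 2,
                module_term_map=[(["a"], "GO:X"), (["b"], "GO:X")],
            )

    def test_deterministic(self):
        genes = [f"g{i}" for i in range(30)]
        a, _ = syn.gen_go_annotations(genes, 3, seed=4)
        b, _ = syn.gen_go_annotations(genes, 3, seed=4)
        assert a.gene_terms == b.gene_terms


class TestGenOrthologWindows:
    def test_expected_identities(self, rng):
        window = syn.random_rna(rng, 100)
        copies, truth = syn.gen_ortholog_windows(window, 6, (40, 60), seed=1)
        site = slice(39, 60)
        site_id = np.mean([
            sum(1 for a, b in zip(c[site], window[site]) if a == b) / 21
            for c in copies
        ])
        flank_cols = list(range(0, 39)) + list(range(60, 100))
        flank_id = np.mean([
            sum(1 for i in flank_cols if c[i] == window[i]) / len(flank_cols)
            for c in copies
        ])
        assert site_id > 0.85
        assert flank_id < 0.75

    def test_deterministic(self, rng):
        window = syn.random_rna(rng, 80)
        a, _ = syn.gen_ortholog_windows(window, 3, (20, 40), seed=5)
        b, _ = syn.gen_ortholog_windows(window, 3, (20, 40), seed=5)
        assert a == b

    def test_bad_offsets(self, rng):
        window = syn.random_rna(rng, 50)
        with pytest.raises(ValidationError):
            syn.gen_ortholog_windows(window, 3, (40, 60), seed=1)

    def test_truth_record_roundtrip(self, rng, tmp_path):
        window = syn.random_rna(rng, 50)
        _copies, truth = syn.gen_ortholog_windows(window, 3, (10, 30), seed=1)
        path = tmp_path / "truth.jsonl"
        syn.write_truths([truth], path)
        back = syn.read_truths(path)
        assert back == [truth]
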