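"""Marker scan: assignments, residual profiles, permutation p-values, BH, block
grouping, cis/trans labels and multi-eQTL forward selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fieldeqtl import eqtl_scan as es
from fieldeqtl.data_io import GenePositions, GenotypePanel
from fieldeqtl.stats import bh_adjust


@pytest.fixture()
def toy_panel():
    alleles = pd.DataFrame(
        {
            "m1": ["P1", "P2", "P2", "P1"],
            "m2": ["P1", "P2", "P1", "P1"],
            "m3": ["P1", "P2", "P1", "P2"],
        },
        index=["P1", "P2", "LA", "LB"],
    )
    mm = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr2"], "pos_bp": [100, 200, 100]},
        index=pd.Index(["m1", "m2", "m3"], name="marker_id"),
    )
    return GenotypePanel(alleles, mm)


class TestAssignment:
    def test_matches_hand_reading_of_the_table(self, toy_panel):
        a = es.assignment_from_marker(toy_panel, "m3")
        assert a.by_line.tolist() == ["P1", "P2", "P1", "P2"]

    def test_background_allele_marker_equals_background_assignment(self, toy_panel):
        a = es.assignment_from_marker(toy_panel, "m2")
        # LA carries P1 at m2 (its background); LB also background -> mismatch only where donor
        assert a.by_line["LA"] == "P1"
        assert (a.by_line.loc[["P1", "P2"]] == ["P1", "P2"]).all()

    def test_samples_follow_their_line(self, toy_panel):
        lines = pd.Series(["LA", "LA", "P2"], index=["s1", "s2", "s3"])
        a = es.assignment_from_marker(toy_panel, "m1", sample_lines=lines)
        assert a.by_sample.tolist() == ["P2", "P2", "P2"]

    def test_unknown_marker_raises(self, toy_panel):
        with pytest.raises(KeyError, match="m9"):
            es.assignment_from_marker(toy_panel, "m9")


class TestScanGene:
    def test_rss_matches_naive_loop_and_background_marker_gives_zero_T(self, tiny_study, tiny_bundle):
        g = next(iter(tiny_study.profiles))
        prof = tiny_study.profiles[g]
        panel = tiny_bundle.panel
        y = tiny_study.expr.log2rpm.loc[g, tiny_study.train_samples.index].to_numpy()
        w = tiny_study.expr.weights.loc[g, tiny_study.train_samples.index].to_numpy()
        from fieldeqtl.envmodel import model_columns, _coef_vector

        ctx = tiny_study.ctx_all
        yh1 = ctx.X[:, model_columns(tiny_study.models_p1[g], ctx)] @ _coef_vector(tiny_study.models_p1[g])
        yh2 = ctx.X[:, model_columns(tiny_study.models_p2[g], ctx)] @ _coef_vector(tiny_study.models_p2[g])
        lines = tiny_study.train_samples["line_id"].to_numpy()
        for mj, marker in list(enumerate(panel.marker_ids))[::7]:
            allele = panel.alleles[marker]
            naive = sum(
                w[i] * (y[i] - (yh2[i] if allele[lines[i]] == "P2" else yh1[i])) ** 2
                for i in range(len(y))
            )
            assert prof.rss[mj] == pytest.approx(naive, abs=1e-9)
        # a synthetic marker column equal to the background split has T == 0
        bg = panel.background.loc[prof.line_ids]
        rss_bg_naive = sum(
            w[i] * (y[i] - (yh2[i] if bg[lines[i]] == "P2" else yh1[i])) ** 2
            for i in range(len(y))
        )
        assert prof.rss_bg == pytest.approx(rss_bg_naive, abs=1e-9)
        bg_like = (panel.alleles.loc[prof.line_ids] == bg.to_numpy()[:, None]).all(axis=0)
        for mj in np.nonzero(bg_like.to_numpy())[0]:
            assert prof.T[mj] == pytest.approx(0.0, abs=1e-9)

    def test_planted_eqtl_maximises_T_within_its_block(self, tiny_study, tiny_bundle):
        truth = tiny_bundle.truth
        hits = 0
        total = 0
        for g, prof in tiny_study.profiles.items():
            t = truth.genes[g]
            if not t.polymorphic:
                continue
            total += 1
            true_i = list(prof.marker_ids).index(t.markers[0])
            # the true marker should sit at (or tie with, or neighbour) the peak
            if prof.T[max(0, true_i - 1): true_i + 2].max() >= prof.T.max() - 1e-9:
                hits += 1
        assert total > 0
        assert hits / total >= 0.8

    def test_scan_invariant_to_marker_and_sample_order(self, tiny_study, tiny_bundle):
        g = next(iter(tiny_study.profiles))
        panel = tiny_bundle.panel
        # shuffle marker columns; GenotypePanel re-sorts by map order
        rng = np.random.default_rng(0)
        cols = rng.permutation(panel.alleles.columns)
        shuffled = GenotypePanel(panel.alleles[cols], panel.marker_map.copy())
        shuffled.heading_days = panel.heading_days
        y = tiny_study.expr.log2rpm.loc[g, tiny_study.train_samples.index].to_numpy()
        w = tiny_study.expr.weights.loc[g, tiny_study.train_samples.index].to_numpy()
        prof2 = es.scan_gene(
            y, w, tiny_study.models_p1[g], tiny_study.models_p2[g],
            shuffled, tiny_study.ctx_all, tiny_study.train_samples["line_id"], gene_id=g,
        )
        np.testing.assert_allclose(prof2.T, tiny_study.profiles[g].T, atol=1e-10)


class TestPermutationPvalues:
    def test_minimum_p_is_one_over_nperm_plus_one(self, tiny_study):
        for perm in tiny_study.perms.values():
            assert perm.marker_p.min() >= 1.0 / (perm.n_perm + 1) - 1e-12
            assert perm.gene_p >= 1.0 / (perm.n_perm + 1) - 1e-12

    def test_all_same_allele_marker_gets_p_one(self, tiny_study, tiny_bundle):
        g = next(iter(tiny_study.profiles))
        prof = tiny_study.profiles[g]
        panel = tiny_bundle.panel
        degenerate = panel.alleles.copy()
        degenerate["m_const"] = "P1"
        mm = panel.marker_map.copy()
        mm.loc["m_const"] = ["chr01", 1]
        panel2 = GenotypePanel(degenerate, mm)
        prof2 = es.scan_gene(
            tiny_study.expr.log2rpm.loc[g, tiny_study.train_samples.index].to_numpy(),
            tiny_study.expr.weights.loc[g, tiny_study.train_samples.index].to_numpy(),
            tiny_study.models_p1[g], tiny_study.models_p2[g], panel2,
            tiny_study.ctx_all, tiny_study.train_samples["line_id"], gene_id=g,
        )
        perm = es.permutation_pvalues(prof2, panel2, n_perm=100, seed=0)
        j = list(prof2.marker_ids).index("m_const")
        assert perm.marker_p[j] == 1.0

    def test_requires_at_least_100_permutations(self, tiny_study, tiny_bundle):
        g = next(iter(tiny_study.profiles))
        with pytest.raises(ValueError, match="at least 100"):
            es.permutation_pvalues(tiny_study.profiles[g], tiny_bundle.panel, n_perm=50)

    def test_stratified_permutations_shuffle_within_background_only(self):
        bg = np.array(["P1"] * 5 + ["P2"] * 4)
        idx = es.stratified_permutations(bg, 50, np.random.default_rng(0))
        assert idx.shape == (50, 9)
        for row in idx:
            assert (bg[row] == bg).all()
            assert sorted(row) == list(range(9))


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.001, 0.002, 0.5])
        np.testing.assert_allclose(q, [0.003, 0.003, 0.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_matches_step_up_definition(self, ps):
        q = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps)
        expect = np.empty(m)
        prev = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            rank = m - rank_from_top
            prev = min(prev, ps[i] * m / rank)
            expect[i] = prev
        np.testing.assert_allclose(q, expect, atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-12).all()


class TestCalls:
    def test_all_p_one_yields_no_calls(self, main_study, main_bundle):
        perms = {
            g: es.ScanPermutations(g, np.ones(len(p.marker_p)), 1.0, p.null_max, p.n_perm)
            for g, p in main_study.perms.items()
        }
        calls = es.call_eqtls(main_study.profiles, perms, main_bundle.panel)
        assert calls == []

    def test_blocks_are_contiguous_with_identical_signatures(self, main_study, main_bundle):
        panel = main_bundle.panel
        order = list(panel.marker_ids)
        for c in main_study.calls:
            idxs = [order.index(m) for m in c.block_markers]
            assert idxs == list(range(min(idxs), max(idxs) + 1))
            # signatures are defined over the scanned lines (parents + CSSLs)
            lines = main_study.profiles[c.gene_id].line_ids
            cols = panel.alleles.loc[lines, list(c.block_markers)].to_numpy()
            assert (cols == cols[:, [0]]).all()
            assert c.q >= c.p - 1e-12
            chroms = set(panel.marker_map.loc[list(c.block_markers), "chrom"])
            assert len(chroms) == 1

    def test_representative_is_max_T_smallest_position(self, main_study, main_bundle):
        panel = main_bundle.panel
        order = list(panel.marker_ids)
        for c in main_study.calls:
            prof = main_study.profiles[c.gene_id]
            Ts = [prof.T[order.index(m)] for m in c.block_markers]
            best = max(Ts)
            candidates = [
                m for m, T in zip(c.block_markers, Ts) if T >= best - 1e-12
            ]
            poss = panel.marker_map.loc[candidates, "pos_bp"]
            assert c.representative == poss.idxmin()


class TestCisTrans:
    def _call(self, chrom, rep_pos, gene="g"):
        return es.EqtlCall(
            gene_id=gene, block_markers=("m",), representative="m", chrom=chrom,
            pos_start=rep_pos, pos_end=rep_pos, statistic=1.0, p=0.01, q=0.02,
            rep_pos=rep_pos,
        )

    @pytest.fixture()
    def positions(self):
        return GenePositions(
            pd.DataFrame({"chrom": ["chr9"], "pos_bp": [10_600_000]},
                         index=pd.Index(["g"], name="gene_id"))
        )

    def test_nearby_same_chromosome_is_cis(self, positions):
        assert es.classify_cis_trans(self._call("chr9", 10_400_000), positions) == "cis"

    def test_other_chromosome_is_trans(self, positions):
        assert es.classify_cis_trans(self._call("chr2", 10_400_000), positions) == "trans"

    def test_same_chromosome_but_distant_is_trans(self, positions):
        assert es.classify_cis_trans(self._call("chr9", 15_600_000), positions) == "trans"

    def test_unknown_gene_position(self, positions):
        call = self._call("chr9", 10_400_000, gene="other")
        assert es.classify_cis_trans(call, positions) == "unknown"


class TestMultiEqtl:
    def test_single_call_selects_itself(self, main_study, main_bundle):
        for g, calls in main_study.calls_by_gene.items():
            if len(calls) == 1:
                sel, rss = es.multi_eqtl_selection(main_study.profiles[g], calls, main_bundle.panel)
                assert [c.representative for c in sel] == [calls[0].representative]
                assert np.isfinite(rss)
                break
        else:
            pytest.skip("no single-call gene in fixture")

    def test_zero_improvement_block_not_selected(self, main_study, main_bundle):
        # duplicating the primary block adds exactly zero reduction
        g = next(iter(main_study.calls_by_gene))
        calls = main_study.calls_by_gene[g]
        primary = calls[0]
        import dataclasses

        clone = dataclasses.replace(primary, statistic=primary.statistic - 1e-6)
        sel, _ = es.multi_eqtl_selection(
            main_study.profiles[g], [primary, clone], main_bundle.panel
        )
        assert len(sel) == 1

    def test_two_locus_gene_recovers_extra_locus(self):
        """For a gene switched to the donor dynamics by either of two loci,
        one block only explains the lines substituted there; forward
        selection should add the second block and strictly lower the
        combined error."""
        from fieldeqtl import run_study, simulate_bundle

        from fieldeqtl import SimConfig

        cfg = SimConfig(seed=19, n_genes=150, frac_polymorphic=0.2, frac_multi_eqtl=1.0,
                        n_sampling_days=6, n_transplant_sets=2)
        bundle = simulate_bundle(cfg)
        res = run_study(bundle, n_perm_poly=200, n_perm_scan=200, seed=5)
        multi_truth = [
            g for g, t in bundle.truth.genes.items() if len(t.markers) == 2
        ]
        picked = [
            g for g in multi_truth
            if g in res.calls_by_gene and len(res.calls_by_gene[g][0].multi_eqtl) > 1
        ]
        for g in picked:
            calls = res.calls_by_gene[g]
            sel, rss = es.multi_eqtl_selection(res.profiles[g], calls, bundle.panel)
            single_rss = float(
                np.where(
                    es.gene_assignment_p2(
                        bundle.panel.alleles.loc[res.profiles[g].line_ids].to_numpy() == "P2",
                        es.call_blocks([calls[0]], bundle.panel.marker_ids),
                    ),
                    res.profiles[g].e_p2,
                    res.profiles[g].e_p1,
                ).sum()
            )
            assert rss < single_rss - 1e-9
        # at least some multi-locus genes should profit from extra blocks
        assert len(picked) >= 1
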