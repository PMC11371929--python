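"""Catalog construction, NNLS refitting and signature-set refinement."""

import numpy as np
import pytest
from scipy.optimize import minimize

from oncointerp import (SimulationConfig, SVRecord, VariantRecord,
                        build_id83_catalog, build_sbs96_catalog,
                        build_sv32_catalog, fit_exposures_nnls,
                        msi_signature_proportion, refine_signature_set,
                        simulate_callset)
from oncointerp.records import IndelFeatures
from oncointerp.signatures import (MutationalCatalog, SignatureReference,
                                   flag_clustered_breakpoints,
                                   mh_deletion_proportion)


def _snv(ref, alt, ctx):
    return VariantRecord(chrom="1", pos=100, ref=ref, alt=alt, tumor_depth=40,
                         tumor_alt=5, normal_depth=20, normal_alt=0,
                         trinucleotide_context=ctx)


class TestCatalogBuilders:
    def test_sbs_channel_increment_and_strand_fold(self):
        cat = build_sbs96_catalog([_snv("C", "T", "ACG"), _snv("G", "A", "CGT")])
        d = cat.as_dict()
        assert d["A[C>T]G"] == 2            # second record folds onto the first
        assert cat.total == 2

    def test_id83_examples(self):
        recs = [
            # 1-bp T deletion in a 6-T homopolymer
            VariantRecord(chrom="1", pos=1, ref="AT", alt="A", tumor_depth=30,
                          tumor_alt=4, indel_features=IndelFeatures(1, 6, 0)),
            # 5-bp deletion with 3-bp microhomology
            VariantRecord(chrom="1", pos=2, ref="ACGTAC", alt="A", tumor_depth=30,
                          tumor_alt=4, indel_features=IndelFeatures(5, 1, 3)),
        ]
        cat = build_id83_catalog(recs)
        d = cat.as_dict()
        assert d["DEL.T.1.6+"] == 1
        assert d["DEL.MH.5+.3"] == 1
        assert mh_deletion_proportion(cat) == pytest.approx(0.5)

    def test_count_conservation_against_generator_tally(self, references):
        cfg = SimulationConfig(seed=5, n_sbs=960, n_indel=400, n_sv=200,
                               artifact_fraction=0.0)
        variants, svs, *_rest, truth = simulate_callset(cfg, references=references)
        snvs = [v for v in variants if v.is_snv]
        indels = [v for v in variants if not v.is_snv]
        np.testing.assert_array_equal(build_sbs96_catalog(snvs).counts,
                                      truth.expected_catalogs["SBS96"].counts)
        np.testing.assert_array_equal(build_id83_catalog(indels).counts,
                                      truth.expected_catalogs["ID83"].counts)
        np.testing.assert_array_equal(build_sv32_catalog(svs).counts,
                                      truth.expected_catalogs["SV32"].counts)

    def test_pure_sbs1_catalog_is_multinomial(self, sbs_ref):
        """Chi-square GOF of generated catalogs against the SBS1 column."""
        from scipy.stats import chisquare
        col = sbs_ref.columns(["SBS1"]).ravel()
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_sbs=960, n_indel=0, n_sv=0,
                                   signature_mixture={"SBS96": {"SBS1": 1.0},
                                                      "ID83": {"ID1": 1.0},
                                                      "SV32": {"RS1": 1.0}},
                                   artifact_fraction=0.0, n_microsat_sites=0)
            variants, *_ = simulate_callset(cfg)
            cat = build_sbs96_catalog([v for v in variants if v.is_snv])
            assert cat.total == 960
            # pool low-expectation channels for test validity
            exp = 960 * col
            order = np.argsort(exp)
            pooled_obs, pooled_exp, acc_o, acc_e = [], [], 0.0, 0.0
            for i in order:
                acc_o += cat.counts[i]
                acc_e += exp[i]
                if acc_e >= 8:
                    pooled_obs.append(acc_o)
                    pooled_exp.append(acc_e)
                    acc_o = acc_e = 0.0
            pooled_obs[-1] += acc_o
            pooled_exp[-1] += acc_e
            _, p = chisquare(pooled_obs, f_exp=pooled_exp)
            assert p > 0.001


class TestClustering:
    def test_isolated_svs_non_clustered(self):
        svs = [SVRecord("1", 1_000_000, "+", "2", 5_000_000, "-", "TRA", 5, 0),
               SVRecord("3", 1_000_000, "+", "3", 1_050_000, "-", "DEL", 5, 0)]
        assert flag_clustered_breakpoints(svs) == [False, False]
        cat = build_sv32_catalog(svs)
        d = cat.as_dict()
        assert d["non-clustered.TRA"] == 1
        assert d["non-clustered.DEL.10-100kb"] == 1

    def test_dense_burst_all_flagged_clustered(self):
        burst = [SVRecord("5", 1_000_000 + 40_000 * i, "+",
                          "5", 1_000_000 + 40_000 * i + 5_000, "-", "DEL", 5, 0)
                 for i in range(20)]
        flags = flag_clustered_breakpoints(burst)
        assert all(flags)
        lone = SVRecord("6", 1_000_000, "+", "6", 1_005_000, "-", "DEL", 5, 0)
        assert flag_clustered_breakpoints(burst + [lone])[-1] is False


class TestNNLS:
    def test_noiseless_two_signature_recovery(self, sbs_ref):
        cols = sbs_ref.columns(["SBS1", "SBS5"])
        catalog = MutationalCatalog("SBS96", 700 * cols[:, 0] + 300 * cols[:, 1])
        exp = fit_exposures_nnls(catalog, sbs_ref, ["SBS1", "SBS5"])
        assert exp.exposures["SBS1"] == pytest.approx(700, abs=1e-6)
        assert exp.exposures["SBS5"] == pytest.approx(300, abs=1e-6)
        assert exp.cosine == pytest.approx(1.0, abs=1e-9)

    def test_zero_catalog(self, sbs_ref):
        exp = fit_exposures_nnls(MutationalCatalog("SBS96", np.zeros(96)), sbs_ref)
        assert exp.degenerate
        assert exp.cosine == 1.0
        assert all(v == 0 for v in exp.exposures.values())

    def test_single_signature_full_attribution(self, sbs_ref):
        col = sbs_ref.columns(["SBS4"]).ravel()
        exp = fit_exposures_nnls(MutationalCatalog("SBS96", 500 * col),
                                 sbs_ref, ["SBS4"])
        assert exp.exposures["SBS4"] == pytest.approx(500, rel=1e-9)
        assert sum(exp.exposures.values()) == pytest.approx(500, rel=1e-6)

    def test_matches_constrained_qp_oracle_on_small_active_sets(self, sbs_ref):
        """The fitted exposures equal an independent bound-constrained quadratic
        program (SLSQP) on instances with <= 4 active signatures."""
        rng = np.random.default_rng(0)
        sets = [["SBS1", "SBS4"], ["SBS1", "SBS5", "SBS13"],
                ["SBS2", "SBS4", "SBS18", "SBS40"]]
        for active in sets:
            M = sbs_ref.columns(active)
            c = rng.integers(0, 200, size=96).astype(float)
            catalog = MutationalCatalog("SBS96", c)
            exp = fit_exposures_nnls(catalog, sbs_ref, active)

            def loss(x):
                return np.sum((M @ x - c) ** 2)
            res = minimize(loss, np.full(len(active), c.sum() / len(active)),
                           bounds=[(0, None)] * len(active), method="SLSQP",
                           options={"ftol": 1e-14, "maxiter": 500})
            oracle = res.x * (c.sum() / res.x.sum())
            got = np.array([exp.exposures[n] for n in active])
            np.testing.assert_allclose(got, oracle,
                                       atol=1e-4 * max(oracle.max(), 1.0))


class TestRefinement:
    def test_well_explained_sample_not_refined(self, sbs_ref):
        rng = np.random.default_rng(1)
        p = sbs_ref.mixture_distribution({"SBS1": 0.4, "SBS5": 0.6})
        catalog = MutationalCatalog("SBS96", rng.multinomial(2000, p))
        exp = refine_signature_set(catalog, sbs_ref, ["SBS1", "SBS5"])
        assert exp.cosine >= 0.90
        assert exp.refinement_trace == []
        assert exp.active_set == ["SBS1", "SBS5"]

    def test_withheld_signature_added(self, sbs_ref):
        """A 40% SBS4 component missing from the initial set is recovered."""
        rng = np.random.default_rng(2)
        p = sbs_ref.mixture_distribution({"SBS1": 0.3, "SBS5": 0.3, "SBS4": 0.4})
        catalog = MutationalCatalog("SBS96", rng.multinomial(3000, p))
        # independent oracle: the fit must be poor without SBS4, good with it
        without = fit_exposures_nnls(catalog, sbs_ref, ["SBS1", "SBS5"])
        with_sbs4 = fit_exposures_nnls(catalog, sbs_ref, ["SBS1", "SBS5", "SBS4"])
        assert without.cosine < 0.90 < with_sbs4.cosine
        exp = refine_signature_set(catalog, sbs_ref, ["SBS1", "SBS5"])
        assert "SBS4" in exp.active_set
        assert "+SBS4" in exp.refinement_trace
        assert exp.cosine >= 0.90
        assert not exp.best_effort

    def test_forward_steps_monotone_in_cosine(self, sbs_ref):
        rng = np.random.default_rng(3)
        p = sbs_ref.mixture_distribution(
            {"SBS1": 0.25, "SBS4": 0.25, "SBS13": 0.25, "SBS18": 0.25})
        catalog = MutationalCatalog("SBS96", rng.multinomial(3000, p))
        exp = refine_signature_set(catalog, sbs_ref, ["SBS1"])
        active = ["SBS1"]
        prev = fit_exposures_nnls(catalog, sbs_ref, active).cosine
        for step in exp.refinement_trace:
            if not step.startswith("+"):
                continue
            active.append(step[1:])
            cos = fit_exposures_nnls(catalog, sbs_ref, active).cosine
            assert cos >= prev
            prev = cos

    def test_cosine_at_exact_trigger_not_refined(self, sbs_ref):
        """The refinement trigger is strict (< 0.90)."""
        from unittest import mock
        catalog = MutationalCatalog(
            "SBS96", 1000 * sbs_ref.columns(["SBS1"]).ravel())
        with mock.patch("oncointerp.signatures.cosine_similarity",
                        return_value=0.90):
            exp = refine_signature_set(catalog, sbs_ref, ["SBS5"])
        assert exp.refinement_trace == []
        assert exp.active_set == ["SBS5"]


class TestMSIProportion:
    def test_definition(self, sbs_ref):
        from oncointerp.signatures import SignatureExposure
        exp = SignatureExposure("SBS96", {"SBS6": 500.0, "SBS1": 500.0},
                                cosine=1.0, active_set=["SBS6", "SBS1"])
        assert msi_signature_proportion(exp) == pytest.approx(0.5)
        none = SignatureExposure("SBS96", {"SBS1": 100.0}, 1.0, ["SBS1"])
        assert msi_signature_proportion(none) == 0.0
        empty = SignatureExposure("SBS96", {}, 1.0, [])
        assert msi_signature_proportion(empty) == 0.0
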