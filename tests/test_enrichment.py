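import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rcre_kit.enrichment import (
    ReporterMeasurement,
    compartment_report,
    nb_wald_test,
    normalized_counts,
    reporter_relative_activity,
    results_frame,
    size_factors,
)
from rcre_kit.io_formats import CountMatrix
from rcre_kit.synth import SimCountSpec, simulate_counts


def _cm(counts: dict, conditions, compartment="cytoplasmic"):
    frame = pd.DataFrame(counts)
    meta = pd.DataFrame(
        {"condition": conditions, "compartment": [compartment] * len(conditions)},
        index=frame.columns,
    )
    return CountMatrix(frame, meta)


class TestSizeFactors:
    def test_exact_twofold_fixture(self):
        cm = _cm({"s1": [10, 100, 50, 7], "s2": [20, 200, 100, 14]}, ["EV", "Rev"])
        sf = size_factors(cm)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_are_unit(self):
        cm = _cm({"s1": [10, 100, 50], "s2": [10, 100, 50]}, ["EV", "Rev"])
        assert size_factors(cm).tolist() == pytest.approx([1.0, 1.0])

    def test_scaling_one_sample_scales_its_factor(self):
        base = {"s1": [11, 120, 53, 400], "s2": [9, 130, 60, 390], "s3": [10, 125, 57, 395]}
        cm = _cm(base, ["EV", "EV", "Rev"])
        sf = size_factors(cm)
        scaled = {k: (np.array(v) * (3 if k == "s3" else 1)).tolist() for k, v in base.items()}
        sf2 = size_factors(_cm(scaled, ["EV", "EV", "Rev"]))
        # relative factors scale by c (absolute factors shift by the common
        # change in the geometric-mean reference, as in the 2x closed form)
        assert (sf2["s3"] / sf2["s1"]) / (sf["s3"] / sf["s1"]) == \
            pytest.approx(3.0, rel=1e-12)
        norm1 = normalized_counts(cm)
        norm2 = normalized_counts(_cm(scaled, ["EV", "EV", "Rev"]))
        pd.testing.assert_frame_equal(
            norm1 / np.exp(np.log(norm1).mean().mean()),
            norm2 / np.exp(np.log(norm2).mean().mean()),
        )

    def test_recovers_simulated_factors_within_ten_percent(self):
        spec = SimCountSpec(n_loci=20, n_replicates=1, baseline_mean=400.0,
                            dispersion=0.02, size_factors=[0.5, 1.0],
                            treatment="Rev", reference="EV")
        # three samples: build manually for factors [0.5, 1, 2]
        rng = np.random.default_rng(30)
        baseline = rng.uniform(200, 800, 20)
        true = np.array([0.5, 1.0, 2.0])
        mu = baseline[:, None] * true[None, :]
        lam = rng.gamma(1 / 0.02, mu * 0.02)
        counts = pd.DataFrame(rng.poisson(lam), columns=["a", "b", "c"])
        sf = size_factors(counts).to_numpy()
        ratio = sf / true
        ratio /= np.exp(np.mean(np.log(ratio)))  # factors are relative
        assert np.all(np.abs(ratio - 1) < 0.10)

    def test_no_all_positive_locus_is_an_error(self):
        cm = _cm({"s1": [0, 5], "s2": [5, 0]}, ["EV", "Rev"])
        with pytest.raises(ValueError, match="positive"):
            size_factors(cm)


class TestNBWaldTest:
    def test_null_is_calibrated_and_near_uniform(self):
        cm, _ = simulate_counts(SimCountSpec(n_loci=200, log2_fc=0.0), seed=31)
        res = nb_wald_test(cm, contrast=("Rev", "EV"))
        p = np.array([r.wald_p for r in res])
        lfc = np.array([r.log2_fc for r in res])
        assert abs(np.median(lfc)) < 0.1
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_fold_change_bias_is_small(self):
        ests = []
        for seed in range(40):
            cm, _ = simulate_counts(
                SimCountSpec(n_loci=20, baseline_mean=500.0, dispersion=0.05,
                             log2_fc=[np.log2(4.2)] + [0.0] * 19), seed=300 + seed)
            ests.append(nb_wald_test(cm)[0].log2_fc)
        assert abs(np.mean(ests) - np.log2(4.2)) < 0.15

    def test_large_effect_is_highly_significant(self):
        cm, _ = simulate_counts(
            SimCountSpec(n_loci=20, baseline_mean=500.0, dispersion=0.05,
                         log2_fc=[np.log2(4.2)] + [0.0] * 19), seed=32)
        top = nb_wald_test(cm)[0]
        assert top.wald_p < 1e-6
        assert top.q >= top.wald_p
        assert top.fold_change == pytest.approx(2.0 ** top.log2_fc)

    def test_all_zero_locus_omitted(self):
        cm = _cm({"s1": [0, 10], "s2": [0, 12], "s3": [0, 9], "s4": [0, 11]},
                 ["EV", "EV", "Rev", "Rev"])
        res = nb_wald_test(cm, factors=pd.Series(1.0, index=cm.sample_ids))
        assert [r.locus_id for r in res] == [1]

    def test_compartment_selection(self):
        frame = pd.DataFrame({
            "t1": [100], "t2": [110], "c1": [400], "c2": [390],
        }, index=["L"])
        meta = pd.DataFrame({
            "condition": ["EV", "Rev", "EV", "Rev"],
            "compartment": ["total", "total", "cytoplasmic", "cytoplasmic"],
        }, index=frame.columns)
        cm = CountMatrix(frame, meta)
        with pytest.raises(ValueError):  # one replicate per group is not enough
            nb_wald_test(cm, compartment="nuclear")

    def test_missing_group_rejected(self):
        cm, _ = simulate_counts(SimCountSpec(n_loci=5), seed=33)
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(cm, contrast=("Tat", "EV"))


class TestCompartmentReport:
    def _results(self, fcs, seed):
        cm, _ = simulate_counts(
            SimCountSpec(n_loci=len(fcs), baseline_mean=800.0, dispersion=0.01,
                         log2_fc=np.log2(fcs).tolist()), seed=seed)
        return nb_wald_test(cm)

    def test_export_enriched_locus_is_flagged(self):
        total = self._results([1.0, 1.0], seed=34)
        cyto = self._results([4.0, 1.0], seed=35)
        report = compartment_report(total, cyto)
        assert bool(report.loc["locus1", "export_enriched"])
        assert not bool(report.loc["locus2", "export_enriched"])

    def test_identical_compartments_have_no_flags(self):
        res = self._results([1.0, 1.0, 1.0], seed=36)
        report = compartment_report(res, res)
        assert not report["export_enriched"].any()

    def test_differing_locus_sets_warn_and_intersect(self):
        total = self._results([1.0, 1.0], seed=37)
        cyto = self._results([1.0], seed=38)
        with pytest.warns(UserWarning, match="intersection"):
            report = compartment_report(total, cyto)
        assert list(report.index) == ["locus1"]

    def test_nuclear_retained_control_pattern(self):
        # a NEAT1-like locus: abundant in total RNA, essentially absent from
        # cytoplasm in every condition -> tiny cytoplasmic/total abundance
        # ratio and no export flag
        total_cm, _ = simulate_counts(
            SimCountSpec(n_loci=2, baseline_mean=[2000.0, 500.0], dispersion=0.01),
            seed=39)
        cyto_cm, _ = simulate_counts(
            SimCountSpec(n_loci=2, baseline_mean=[5.0, 500.0], dispersion=0.01,
                         compartment="cytoplasmic"), seed=40)
        total = nb_wald_test(total_cm, factors=pd.Series(1.0, index=total_cm.sample_ids))
        cyto = nb_wald_test(cyto_cm, factors=pd.Series(1.0, index=cyto_cm.sample_ids))
        ft, fc = results_frame(total), results_frame(cyto)
        ratio = fc.loc["locus1", "base_mean"] / ft.loc["locus1", "base_mean"]
        assert ratio < 0.05
        report = compartment_report(total, cyto)
        assert not report.loc["locus1", "export_enriched"]


class TestReporter:
    def _measure(self, pair, p24, seap):
        return ReporterMeasurement(f"s_{pair}", pair, p24, seap)

    def test_reference_pair_maps_to_exactly_one(self):
        ms = [self._measure("Rec/prRcRE", 6.4, 1e5), self._measure("Rev/CEBPZ", 9.1, 1.3e5)]
        acts = reporter_relative_activity(ms, "Rec/prRcRE")
        assert acts[0].activity == 1.0

    def test_double_p24_doubles_activity(self):
        ms = [self._measure("Rec/prRcRE", 6.4, 1e5), self._measure("x", 12.8, 1e5)]
        assert reporter_relative_activity(ms)[1].activity == pytest.approx(2.0)

    def test_double_seap_halves_activity(self):
        ms = [self._measure("Rec/prRcRE", 6.4, 1e5), self._measure("x", 6.4, 2e5)]
        assert reporter_relative_activity(ms)[1].activity == pytest.approx(0.5)

    def test_invariant_to_common_seap_rescaling(self):
        ms = [self._measure("Rec/prRcRE", 6.4, 1e5), self._measure("x", 3.2, 2e5)]
        scaled = [ReporterMeasurement(m.sample_id, m.pair, m.p24, m.seap * 7.5) for m in ms]
        a1 = [a.activity for a in reporter_relative_activity(ms)]
        a2 = [a.activity for a in reporter_relative_activity(scaled)]
        assert a1 == pytest.approx(a2)

    def test_zero_seap_rejected(self):
        with pytest.raises(ValueError):
            ReporterMeasurement("s", "x", 1.0, 0.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            reporter_relative_activity([self._measure("x", 1.0, 1.0)], "Rec/prRcRE")
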