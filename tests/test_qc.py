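"""Correction-factor calibration, PAF computation and the SNP filter cascade,
checked against closed forms and a hand-computed 10-SNP oracle."""

import numpy as np
import pandas as pd
import pytest

import poolgwas as pg
from poolgwas.qc import EstimationError, QCThresholds, _variance_diff_fail
from poolgwas.synthetic import BeadArrayMeasurement


def probes_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "probe_index", "red", "green"])


def array_of(rows, **kw):
    defaults = dict(array_id="a0", pool_id="pool1", group="case", strand="top")
    defaults.update(kw)
    return BeadArrayMeasurement(probes=probes_frame(rows), **defaults)


class TestCorrectionFactor:
    def test_single_snp_closed_form(self):
        # 300/(300 + 900/corr) = 0.5  =>  corr = 3
        arr = array_of([("s1", 0, 300.0, 900.0)])
        assert pg.compute_correction_factor(arr) == pytest.approx(3.0, abs=1e-4)

    def test_symmetric_balanced_set_needs_no_correction(self, make_array_fn):
        arr = make_array_fn({"s1": 0.3, "s2": 0.7, "s3": 0.1, "s4": 0.9})
        assert pg.compute_correction_factor(arr) == pytest.approx(1.0, abs=1e-5)

    def test_recovers_generative_imbalance(self):
        # symmetric frequency set measured with green channel doubled
        rows = []
        for i, p in enumerate([0.2, 0.8, 0.35, 0.65, 0.5]):
            for j in range(6):
                rows.append((f"s{i}", j, 1000 * p, 2.0 * 1000 * (1 - p)))
        arr = array_of(rows)
        assert pg.compute_correction_factor(arr) == pytest.approx(2.0, abs=1e-4)

    def test_calibration_invariant(self, panel50, small_cohort):
        frac = pg.construct_pool(small_cohort, small_cohort.case_ids, 0.0, seed=0)
        arr = pg.simulate_arrays(
            frac, panel50.set_index("snp_id")["expected_probes"], 1, "p", "case",
            channel_imbalance=1.7, noise_cv=0.05, negative_rate=0.02, seed=3,
        )[0]
        corr = pg.compute_correction_factor(arr)
        paf = pg.compute_paf(arr, corr)
        assert paf["paf"].mean() == pytest.approx(0.5, abs=1e-6)

    def test_all_probes_negative_is_estimation_error(self):
        arr = array_of([("s1", 0, -5.0, -9.0), ("s1", 1, -2.0, -1.0)])
        with pytest.raises(EstimationError):
            pg.compute_correction_factor(arr)

    def test_no_root_in_bracket(self):
        # red == 0 everywhere: PAF is 0 for every corr, mean can never reach 0.5
        arr = array_of([("s1", 0, 0.0, 900.0)])
        with pytest.raises(EstimationError):
            pg.compute_correction_factor(arr)


class TestComputePaf:
    @pytest.mark.parametrize(
        "red,green,corr,expected",
        [(600, 600, 1.0, 0.5), (900, 300, 1.0, 0.75), (300, 900, 3.0, 0.5)],
    )
    def test_formula(self, red, green, corr, expected):
        arr = array_of([("s1", 0, float(red), float(green))])
        paf = pg.compute_paf(arr, corr)
        assert paf.loc[0, "paf"] == pytest.approx(expected, abs=1e-12)

    def test_negative_probes_excluded(self):
        arr = array_of([("s1", 0, 600.0, 600.0), ("s1", 1, -100.0, 600.0)])
        paf = pg.compute_paf(arr, 1.0)
        assert paf.loc[0, "paf"] == pytest.approx(0.5)
        assert paf.loc[0, "n_probes_used"] == 1

    def test_no_usable_probes_gives_missing(self):
        arr = array_of([("s1", 0, -1.0, -1.0), ("s2", 0, 500.0, 1500.0)])
        paf = pg.compute_paf(arr, 1.0).set_index("snp_id")
        assert np.isnan(paf.loc["s1", "paf"]) and paf.loc["s1", "n_probes_used"] == 0
        assert paf.loc["s2", "paf"] == pytest.approx(0.25)

    def test_range(self, panel50, small_cohort):
        frac = pg.construct_pool(small_cohort, small_cohort.case_ids, 0.0, seed=0)
        arr = pg.simulate_arrays(
            frac, panel50.set_index("snp_id")["expected_probes"], 1, "p", "case",
            noise_cv=0.2, negative_rate=0.05, seed=5,
        )[0]
        paf = pg.compute_paf(arr, 1.3)["paf"].dropna()
        assert paf.between(0, 1).all()

    def test_invalid_corr(self):
        with pytest.raises(ValueError):
            pg.compute_paf(array_of([("s1", 0, 1.0, 1.0)]), 0.0)


def _paf_table_corr1(arrays):
    """PAF table at the generative correction factor (balanced channels)."""
    frames = []
    for arr in arrays:
        paf = pg.compute_paf(arr, 1.0)
        paf.insert(1, "pool_id", arr.pool_id)
        paf.insert(2, "group", arr.group)
        paf.insert(3, "array_id", arr.array_id)
        paf.insert(4, "strand", arr.strand)
        frames.append(paf)
    return pd.concat(frames, ignore_index=True)


def _oracle_setup():
    """10-SNP hand-built scenario exercising every filter rule.

    Balanced channels (corr = 1), 10 probes at intensity 2000 unless a
    rule needs otherwise, two arrays per group so the variance rule has
    replicates, and identical case/control frequencies (null SNPs).
    """
    panel = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(10)],
            "chrom": ["1", "2", "3", "4", "X", "6", "7", "8", "9", "10"],
            "pos": np.arange(1, 11) * 1000,
            "ref_af": [0.30, 0.005, 0.70, 0.40, 0.60, 0.45, 0.55, 0.20, 0.20, 0.80],
            "expected_probes": [10] * 10,
        }
    )
    # s6 concordance: true PAF 0.855 vs ref 0.55 -> |diff| = 0.305 > 0.3
    # s7 boundary:    true PAF 0.50 vs ref 0.20 -> |diff| = 0.30 (retained)
    base = {"s0": 0.30, "s1": 0.30, "s2": 0.70, "s3": 0.40, "s4": 0.60,
            "s5": 0.45, "s6": 0.855, "s7": 0.50, "s8": 0.20, "s9": 0.80}

    def build(group, aid, var_bump=0.0, jitter=0.0):
        rows = []
        for snp in panel["snp_id"]:
            p = min(base[snp] + (var_bump if snp == "s9" else 0.0), 1.0)
            n_probes = 3 if snp == "s5" else 10  # s5: 3 <= 10/3 probes
            intensity = 1100.0 if snp == "s3" else 2000.0  # s3: sum below 1200
            for j in range(n_probes):
                red, green = intensity * p, intensity * (1 - p)
                if snp == "s9":
                    red *= 1 + jitter
                if snp == "s2" and j < 2:  # s2: 2/10 probes negative (>10%)
                    red, green = -red, -green
                rows.append((snp, j, red, green))
        return array_of(rows, array_id=aid, group=group)

    arrays = [
        build("case", "c0"),
        build("case", "c1", var_bump=0.15),  # s9: case replicate variance blow-up
        # tiny control-side jitter keeps the F-test denominator non-zero
        build("control", "u0", jitter=1e-4),
        build("control", "u1", jitter=-1e-4),
    ]
    return panel, arrays


@pytest.fixture(scope="module")
def oracle():
    panel, arrays = _oracle_setup()
    paf_table = _paf_table_corr1(arrays)
    report = pg.apply_snp_filters(paf_table, arrays, panel).set_index("snp_id")
    return panel, arrays, report


class TestFilterCascade:

    def test_expected_flags(self, oracle):
        _, _, rep = oracle
        expected_fail = {
            "s1": "maf_panel",          # panel MAF 0.5% <= 1%
            "s2": "negative_probes",    # 20% negative beadscores
            "s3": "intensity_sum",      # mean red+green = 1100 < 1200
            "s4": "autosome",           # chromosome X
            "s5": "probe_count",        # 3 probes, needs > 10/3
            "s6": "ref_af_concordance", # |PAF - ref| = 0.305 > 0.3
            "s9": "variance_diff",      # case replicate variance blow-up
        }
        for snp, rule in expected_fail.items():
            assert not rep.loc[snp, rule], f"{snp} should fail {rule}"
            assert not rep.loc[snp, "retained"]
        for snp in ["s0", "s7", "s8"]:
            assert rep.loc[snp, "retained"], f"{snp} should be retained"

    def test_each_rule_fails_only_its_snp(self, oracle):
        _, _, rep = oracle
        for rule, bad in [
            ("maf_panel", {"s1"}), ("negative_probes", {"s2"}),
            ("intensity_sum", {"s3"}), ("autosome", {"s4"}),
            ("probe_count", {"s5"}), ("ref_af_concordance", {"s6"}),
            ("variance_diff", {"s9"}),
        ]:
            assert set(rep.index[~rep[rule]]) == bad

    def test_concordance_boundary_inclusive(self, oracle):
        # |PAF - ref| = 0.30 exactly is retained; 0.305 is excluded
        _, _, rep = oracle
        assert rep.loc["s7", "ref_af_concordance"]
        assert not rep.loc["s6", "ref_af_concordance"]

    def test_retained_is_conjunction(self, oracle):
        _, _, rep = oracle
        rules = [c for c in rep.columns if c != "retained"]
        assert (rep["retained"] == rep[rules].all(axis=1)).all()

    def test_unmatched_snp_flagged(self, oracle):
        panel, arrays, _ = oracle
        extra = array_of([("ghost", 0, 900.0, 900.0)], array_id="c9")
        paf_table = _paf_table_corr1(arrays + [extra])
        rep = pg.apply_snp_filters(paf_table, arrays + [extra], panel).set_index("snp_id")
        assert not rep.loc["ghost", "matched"]
        assert not rep.loc["ghost", "retained"]

    def test_negative_threshold_monotonicity(self, oracle):
        panel, arrays, _ = oracle
        paf_table = _paf_table_corr1(arrays)
        kept = []
        for neg_max in [0.30, 0.15, 0.05, 0.0]:
            rep = pg.apply_snp_filters(
                paf_table, arrays, panel, QCThresholds(neg_max=neg_max)
            )
            kept.append(rep["retained"].sum())
        assert kept == sorted(kept, reverse=True)

    def test_probe_count_boundary_strict(self):
        # exactly half the expected probes fails for a 1-5% MAF SNP
        panel = pd.DataFrame({
            "snp_id": ["a", "b"], "chrom": ["1", "2"], "pos": [1, 2],
            "ref_af": [0.03, 0.97], "expected_probes": [10, 10],
        })
        rows = [("a", j, 1000.0 * 0.03, 1000.0 * 0.97) for j in range(5)]
        rows += [("b", j, 1000.0 * 0.97, 1000.0 * 0.03) for j in range(10)]
        arr = array_of(rows)
        paf_table = _paf_table_corr1([arr])
        rep = pg.apply_snp_filters(
            paf_table, [arr], panel, QCThresholds(intensity_min=900.0)
        ).set_index("snp_id")
        assert not rep.loc["a", "probe_count"]  # 5 == 10/2, "over half" fails
        assert rep.loc["b", "probe_count"]


class TestRecovery:
    def test_zero_noise_chain_recovers_truth_exactly(self, panel50, small_cohort):
        # at the generative correction factor (balanced channels: corr = 1)
        exp = panel50.set_index("snp_id")["expected_probes"]
        arrays = []
        for group, ids in [("case", small_cohort.case_ids),
                           ("control", small_cohort.control_ids)]:
            frac = pg.construct_pool(small_cohort, ids, 0.0, seed=0)
            arrays += pg.simulate_arrays(
                frac, exp, 2, "pool1", group, channel_imbalance=1.0,
                noise_cv=0.0, negative_rate=0.0, probe_count_jitter=0.0, seed=1,
            )
        paf_table = _paf_table_corr1(arrays)
        summary = pg.summarize_paf(paf_table)
        for group, ids in [("case", small_cohort.case_ids),
                           ("control", small_cohort.control_ids)]:
            truth = pg.construct_pool(small_cohort, ids, 0.0, seed=0)
            est = summary[summary.group == group].set_index("snp_id")["mean_paf"]
            assert np.abs(est - truth.loc[est.index]).max() < 1e-12

    def test_run_qc_retains_clean_snps(self, panel50, small_cohort):
        exp = panel50.set_index("snp_id")["expected_probes"]
        arrays = []
        for group, ids in [("case", small_cohort.case_ids),
                           ("control", small_cohort.control_ids)]:
            frac = pg.construct_pool(small_cohort, ids, 0.0, seed=0)
            arrays += pg.simulate_arrays(
                frac, exp, 2, "pool1", group, channel_imbalance=1.4,
                noise_cv=0.03, negative_rate=0.01, seed=2,
            )
        kept, report = pg.run_qc(arrays, panel50)
        assert report["retained"].sum() >= 45  # only sporadic failures
        assert set(kept["snp_id"]) == set(report.loc[report.retained, "snp_id"])
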