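"""Livak fold-change quantification, significance, linker correlation, report."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

import beldyad as bd
from beldyad.induction import stars_for


def ct_table(rows):
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "target_ct", "reference_ct"])


class TestFoldChange:
    def test_identical_delta_ct_gives_unit_fold_change(self):
        t = ct_table(
            [("g", "WT", i, 25.0, 18.0) for i in (1, 2, 3)]
            + [("g", "transgenic", i, 25.0, 18.0) for i in (1, 2, 3)]
        )
        r = bd.fold_change(t, "g")
        assert r.fold_change == pytest.approx(1.0)

    def test_known_ddct_closed_form(self):
        # ddCt = -1 -> fold change 2
        t = ct_table(
            [("g", "WT", i, 25.0, 18.0) for i in (1, 2)]
            + [("g", "transgenic", i, 24.0, 18.0) for i in (1, 2)]
        )
        r = bd.fold_change(t, "g")
        assert r.fold_change == pytest.approx(2.0)
        assert r.log2_fold_change == pytest.approx(1.0)

    def test_mean_form_equals_ratio_form_noiseless(self):
        """2^-ddCt from replicate means equals the per-condition ratio of
        normalised quantities 2^-(dCt) on noiseless data."""
        t = ct_table(
            [("g", "WT", i, 26.0, 19.0) for i in (1, 2, 3)]
            + [("g", "transgenic", i, 23.5, 19.0) for i in (1, 2, 3)]
        )
        r = bd.fold_change(t, "g")
        ratio = 2.0 ** -(23.5 - 19.0) / 2.0 ** -(26.0 - 19.0)
        assert r.fold_change == pytest.approx(ratio)

    def test_single_replicate_fc_computed_p_missing(self):
        t = ct_table([("g", "WT", 1, 25.0, 18.0), ("g", "transgenic", 1, 23.0, 18.0)])
        r = bd.fold_change(t, "g")
        assert r.fold_change == pytest.approx(4.0)
        assert math.isnan(r.p_value) and r.stars == 0

    def test_missing_condition_errors(self):
        t = ct_table([("g", "WT", 1, 25.0, 18.0)])
        with pytest.raises(ValueError, match="condition"):
            bd.fold_change(t, "g")

    def test_efficiency_corrected_base(self):
        t = ct_table(
            [("g", "WT", i, 25.0, 18.0) for i in (1, 2)]
            + [("g", "transgenic", i, 24.0, 18.0) for i in (1, 2)]
        )
        r = bd.fold_change(t, "g", efficiency=0.9)
        assert r.fold_change == pytest.approx(1.9)

    def test_welch_flag_runs(self):
        t = ct_table(
            [("g", "WT", i, 25.0 + 0.1 * i, 18.0) for i in (1, 2, 3)]
            + [("g", "transgenic", i, 23.0 + 0.3 * i, 18.0) for i in (1, 2, 3)]
        )
        r_pooled = bd.fold_change(t, "g", equal_var=True)
        r_welch = bd.fold_change(t, "g", equal_var=False)
        assert r_pooled.fold_change == r_welch.fold_change
        assert r_pooled.p_value != r_welch.p_value

    def test_stars_thresholds(self):
        assert [stars_for(p) for p in (0.2, 0.04, 0.009, 0.0009, float("nan"))] == [0, 1, 2, 3, 0]

    def test_wt_vs_wt_expectation_unity(self):
        """Under the null (true FC 1) the mean log2 fold change over 1000
        simulated tables is 0 within 3 standard errors."""
        logs = []
        for seed in range(1000):
            t = bd.simulate_ct_table(bd.QpcrSimSpec(("g",), {}, 3, 0.3, seed=seed))
            logs.append(bd.fold_change(t, "g").log2_fold_change)
        se = np.std(logs, ddof=1) / np.sqrt(len(logs))
        assert abs(np.mean(logs)) < 3 * se

    def test_parameter_recovery_within_simulation_bound(self):
        """Median absolute relative error of recovered fold changes stays
        below a bound the simulation oracle itself establishes (direct
        normal draws of ddCt at the same noise level), with 25% slack."""
        sd, n_rep, fc_true = 0.3, 3, 5.0
        errs = []
        for seed in range(1000):
            t = bd.simulate_ct_table(bd.QpcrSimSpec(("g",), {"g": fc_true}, n_rep, sd, seed=seed))
            errs.append(abs(bd.fold_change(t, "g").fold_change - fc_true) / fc_true)
        # oracle: ddCt estimate ~ N(0, 4 sd^2 / n) around the truth
        rng = np.random.default_rng(1)
        sd_ddct = math.sqrt(4 * sd**2 / n_rep)
        oracle = np.median(np.abs(2.0 ** rng.normal(0, sd_ddct, 100_000) - 1))
        assert np.median(errs) <= 1.25 * oracle


class TestLinkerCorrelation:
    @staticmethod
    def results(fcs):
        return [
            bd.FoldChangeResult(g, fc, math.log2(fc), 0.01, 2, 3, 3)
            for g, fc in fcs.items()
        ]

    def test_strictly_decreasing_gives_minus_one(self):
        rho, _ = bd.linker_induction_correlation(
            self.results({"a": 9.0, "b": 5.0, "c": 3.0, "d": 1.5}),
            {"a": 0, "b": 1, "c": 4, "d": 12},
        )
        assert rho == pytest.approx(-1.0)

    def test_strictly_increasing_gives_plus_one(self):
        rho, _ = bd.linker_induction_correlation(
            self.results({"a": 1.5, "b": 3.0, "c": 5.0}),
            {"a": 0, "b": 4, "c": 12},
        )
        assert rho == pytest.approx(1.0)

    def test_constant_fold_changes_undefined(self):
        rho, p = bd.linker_induction_correlation(
            self.results({"a": 2.0, "b": 2.0, "c": 2.0}),
            {"a": 0, "b": 4, "c": 12},
        )
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match=">= 3"):
            bd.linker_induction_correlation(self.results({"a": 2.0, "b": 3.0}), {"a": 0, "b": 1})

    def test_sign_recovery_under_noise(self):
        """With a monotone >= 2-fold span the Spearman sign matches the
        generating trend in > 99% of seeded simulations."""
        fcs = {"a": 8.0, "b": 4.0, "c": 2.0, "d": 1.0}
        linkers = {"a": 0, "b": 1, "c": 4, "d": 12}
        negative = 0
        n_sims = 400
        for seed in range(n_sims):
            t = bd.simulate_ct_table(bd.QpcrSimSpec(tuple(fcs), fcs, 3, 0.3, seed=seed))
            rho, _ = bd.linker_induction_correlation(bd.fold_change_table(t), linkers)
            negative += rho < 0
        assert negative / n_sims > 0.99


class TestInductionReport:
    @staticmethod
    def scan_frame(rows):
        return pd.DataFrame(rows, columns=["gene_id", "orientation", "linker_length"])

    def test_motif_absent_genes_flagged(self):
        scan = self.scan_frame(
            [("StIAA3", "TtH", 0), ("StIAA14", "HtT", 1), ("StIAA22", "HtH", 4), ("StIAA24", "TtT", 12)]
        )
        results = [
            bd.FoldChangeResult(g, fc, math.log2(fc), 0.01, 2, 3, 3)
            for g, fc in [("StIAA3", 6.0), ("StIAA14", 4.0), ("StIAA22", 3.0),
                          ("StIAA24", 2.0), ("StIAA4", 1.0), ("StIAA5", 1.1)]
        ]
        report = bd.induction_report(scan, results)
        absent = set(report.loc[~report["motif_present"], "gene"])
        assert absent == {"StIAA4", "StIAA5"}

    def test_empty_scan_output_all_absent(self):
        results = [bd.FoldChangeResult("g", 1.0, 0.0, 0.5, 0, 3, 3)]
        report = bd.induction_report(self.scan_frame([]), results)
        assert not report["motif_present"].any()

    def test_mismatched_ids_warn(self, caplog):
        scan = self.scan_frame([("other", "TtH", 0)])
        results = [bd.FoldChangeResult("g", 1.0, 0.0, 0.5, 0, 3, 3)]
        with caplog.at_level(logging.WARNING):
            report = bd.induction_report(scan, results)
        assert "other" in caplog.text
        assert list(report["gene"]) == ["g"]
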