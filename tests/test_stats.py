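import numpy as np
import pandas as pd
import pytest

from tmjvol.reference_values import ESTIMATED_MEANS, TIMEPOINTS
from tmjvol.stats import (
    TimeCourseFit,
    fit_time_course,
    format_p,
    format_results_text,
    make_results_table,
    pairwise_contrasts,
    read_records,
)
from tmjvol.synth import SimSpec, default_covariance, simulate_longitudinal_records

VJS_MEANS = np.array([ESTIMATED_MEANS["Vjs"][tp] for tp in TIMEPOINTS])


def long_records(Y: np.ndarray, outcome: str = "Vjs") -> pd.DataFrame:
    """Wide (n_joints, 4) matrix (NaN = missing) -> long records."""
    rows = []
    for j, vals in enumerate(Y):
        for tp, v in zip(TIMEPOINTS, vals):
            if not np.isnan(v):
                rows.append((f"P{j // 2}", f"J{j}", tp, outcome, float(v)))
    return pd.DataFrame(
        rows, columns=["patient_id", "joint_id", "timepoint", "outcome", "value_mm3"]
    )


def mvn_sample(rng, n, means, cov):
    return rng.multivariate_normal(means, cov, size=n)


@pytest.fixture
def balanced(rng):
    return mvn_sample(rng, 60, VJS_MEANS, default_covariance("Vjs", 0.6))


class TestFitCompleteData:
    def test_saturated_means_identity(self, balanced):
        fit = fit_time_course(long_records(balanced), "Vjs")
        assert np.abs(fit.means - balanced.mean(axis=0)).max() < 1e-6

    def test_reml_covariance_is_sample_covariance(self, balanced):
        fit = fit_time_course(long_records(balanced), "Vjs")
        centered = balanced - balanced.mean(axis=0)
        assert np.allclose(fit.covariance, centered.T @ centered / (len(balanced) - 1))

    def test_ml_divisor(self, balanced):
        fit = fit_time_course(long_records(balanced), "Vjs", reml=False)
        centered = balanced - balanced.mean(axis=0)
        assert np.allclose(fit.covariance, centered.T @ centered / len(balanced))

    def test_se_is_sigma_over_n(self, balanced):
        fit = fit_time_course(long_records(balanced), "Vjs")
        assert np.allclose(fit.ses, np.sqrt(np.diag(fit.covariance) / len(balanced)))

    def test_validation_errors(self, balanced):
        with pytest.raises(ValueError, match="at least 2 joints"):
            fit_time_course(long_records(balanced[:1]), "Vjs")
        with pytest.raises(ValueError, match="no records"):
            fit_time_course(long_records(balanced), "Vpjs")
        Y = balanced[:5].copy()
        Y[0, 1:] = np.nan  # joint with a single observation
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_time_course(long_records(Y), "Vjs")

    def test_duplicate_records_rejected(self, balanced):
        df = long_records(balanced[:4])
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            fit_time_course(dup, "Vjs")


class TestFitMissingData:
    def test_reml_loglik_nondecreasing(self, rng):
        Y = mvn_sample(rng, 80, VJS_MEANS, default_covariance("Vjs", 0.6))
        Y[: 40, 1] = np.nan
        fit = fit_time_course(long_records(Y), "Vjs")
        hist = fit.ll_history
        assert len(hist) > 1
        assert all(b >= a - 1e-6 for a, b in zip(hist, hist[1:]))

    def test_mar_recovery_beats_complete_case(self, rng):
        # T1 deleted for the half of joints with the highest T0 values:
        # under MAR the likelihood fit should de-bias the T1 mean
        cov = default_covariance("Vjs", 0.7)
        Y = mvn_sample(rng, 400, VJS_MEANS, cov)
        cut = np.quantile(Y[:, 0], 0.5)
        Ymis = Y.copy()
        Ymis[Y[:, 0] > cut, 1] = np.nan
        truth = VJS_MEANS[1]
        fit = fit_time_course(long_records(Ymis), "Vjs")
        cc_mean = np.nanmean(Ymis[:, 1])
        assert abs(fit.means[1] - truth) < abs(cc_mean - truth)

    def test_complete_case_flag(self, rng):
        Y = mvn_sample(rng, 50, VJS_MEANS, default_covariance("Vjs", 0.6))
        Y[:20, 1] = np.nan
        fit = fit_time_course(long_records(Y), "Vjs", complete_case=True)
        assert fit.n_joints == 30
        assert np.all(fit.n_obs == 30)

    def test_cs_structure(self, rng):
        Y = mvn_sample(rng, 60, VJS_MEANS, default_covariance("Vjs", 0.5))
        Y[:25, 1] = np.nan
        fit = fit_time_course(long_records(Y), "Vjs", cov_structure="cs")
        assert fit.cov_structure == "cs"
        # compound symmetry: all off-diagonal correlations equal
        d = np.sqrt(np.diag(fit.covariance))
        corr = fit.covariance / np.outer(d, d)
        off = corr[np.triu_indices(4, 1)]
        assert np.allclose(off, off[0], atol=1e-6)

    def test_patient_intercept_runs(self, rng):
        spec = SimSpec(seed=11, n_patients=25, between_side_correlation=0.6)
        df = simulate_longitudinal_records(spec)
        default = fit_time_course(df, "Vjs")
        clustered = fit_time_course(df, "Vjs", patient_intercept=True)
        assert clustered.cov_structure == "unstructured+patient"
        # means agree closely; only the dependence model differs
        assert np.abs(default.means - clustered.means).max() < 0.05 * default.means.mean()


class TestContrasts:
    def make_fit(self, means, cov_means):
        cov_means = np.asarray(cov_means, dtype=float)
        return TimeCourseFit(
            outcome="Vjs", means=np.asarray(means, dtype=float),
            ses=np.sqrt(np.diag(cov_means)), cov_means=cov_means,
            covariance=cov_means * 70, overall_stat=0.0, overall_p=1.0,
            loglik=0.0, ll_history=[0.0], n_joints=70,
            n_obs=np.array([70, 38, 70, 70]), cov_structure="unstructured",
            reml=True, converged=True,
        )

    def test_published_sign_convention(self):
        fit = self.make_fit(VJS_MEANS, np.eye(4))
        cons = {(c.earlier, c.later): c for c in pairwise_contrasts(fit)}
        assert cons[("T0", "T1")].difference > 0  # T1 exceeds T0 -> positive
        assert cons[("T1", "T2")].difference < 0  # recedes after T1 -> negative
        assert cons[("T0", "T1")].difference == pytest.approx(348.22, abs=1e-9)

    def test_equal_means_display_cap(self):
        fit = self.make_fit([5.0] * 4, np.eye(4) * 2.0)
        for c in pairwise_contrasts(fit):
            assert c.p_adjusted == 1.0
            assert format_p(c.p_adjusted) == "> .9999"

    def test_bonferroni_arithmetic_and_monotonicity(self):
        fit = self.make_fit([0.0, 2.5758293, 0.0, 0.0], np.eye(4) * 0.5)
        cons = pairwise_contrasts(fit)
        for c in cons:
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted <= 1.0
        c01 = cons[0]  # z = 2.5758... -> raw p = 0.01
        assert c01.p_raw == pytest.approx(0.01, abs=1e-6)
        assert c01.p_adjusted == pytest.approx(0.06, abs=1e-5)

    def test_t_reference_option(self):
        fit = self.make_fit([0.0, 1.0, 0.0, 0.0], np.eye(4) * 0.25)
        normal = pairwise_contrasts(fit)[0]
        heavy = pairwise_contrasts(fit, df=5)[0]
        assert heavy.p_raw > normal.p_raw


class TestResultsTable:
    @pytest.fixture
    def fit(self, rng):
        Y = mvn_sample(rng, 70, VJS_MEANS, default_covariance("Vjs", 0.8))
        return fit_time_course(long_records(Y), "Vjs")

    def test_p_formatting(self):
        assert format_p(3e-6) == "< .0001*"
        assert format_p(0.99999) == "> .9999"
        assert format_p(0.0023) == "0.0023"
        assert format_p(1e-4) == "0.0001*"

    def test_layout(self, fit):
        table = make_results_table(fit)
        assert len(table) == 6
        assert table.loc[0, "outcome"] == "Vjs"
        assert list(table["posthoc"]) == [
            "T0 versus T1", "T0 versus T2", "T0 versus T3",
            "T1 versus T2", "T1 versus T3", "T2 versus T3",
        ]
        assert pd.isna(table.loc[4, "estimated_mean"])

    def test_csv_roundtrip_exact(self, fit, tmp_path):
        table = make_results_table(fit)
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        for col in ("estimated_mean", "mean_se", "difference", "diff_se"):
            a, b = table[col].to_numpy(float), back[col].to_numpy(float)
            assert np.array_equal(a, b, equal_nan=True)
        assert list(back["p_bonferroni"]) == list(table["p_bonferroni"])

    def test_text_rendition(self, fit):
        text = format_results_text(make_results_table(fit))
        assert "Estimated mean (SE)" in text
        assert "T2 versus T3" in text


class TestReadRecords:
    def test_missing_columns(self, tmp_path):
        path = tmp_path / "r.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_records(path)

    def test_roundtrip(self, tmp_path, rng):
        df = long_records(mvn_sample(rng, 4, VJS_MEANS, np.eye(4)))
        path = tmp_path / "r.csv"
        df.to_csv(path, index=False)
        back = read_records(path)
        assert len(back) == len(df)
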