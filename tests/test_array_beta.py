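"""Beta values, masking, Epanechnikov density and peak-based correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone as sk_clone

from methpanel.array_beta import (
    BetaMatrix,
    DegenerateDistributionError,
    PeakBasedCorrector,
    PeakEstimate,
    compute_beta,
    correct_cohort,
    epanechnikov_density,
    find_peaks,
    mask_unreliable,
    pbc_transform,
    silverman_bandwidth,
)
from methpanel.simulate import SimTruth, gen_beta_cohort


class TestComputeBeta:
    @pytest.mark.parametrize(
        "M, U, expected", [(300, 100, 0.75), (0, 500, 0.0), (7, 7, 0.5), (1e5, 1e5, 0.5)]
    )
    def test_fraction_of_methylated_signal(self, M, U, expected):
        assert compute_beta(M, U) == pytest.approx(expected)

    def test_zero_total_intensity_is_missing_not_error(self):
        assert np.isnan(compute_beta(0.0, 0.0))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(-1.0, 5.0)


class TestMaskUnreliable:
    @pytest.mark.parametrize(
        "p, beads, kept",
        [(0.051, 10, False), (0.05, 3, True), (0.01, 2, False), (0.0, 3, True)],
    )
    def test_detection_and_bead_rules(self, p, beads, kept):
        out = mask_unreliable(0.5, p, beads)
        assert (not np.isnan(out)) is kept


class TestEpanechnikovDensity:
    def test_single_value_closed_form(self):
        grid, dens = epanechnikov_density([0.5], bandwidth=0.1, grid=np.array([0.5, 0.61]))
        assert dens[0] == pytest.approx(7.5)
        assert dens[1] == 0.0

    def test_symmetry_about_midpoint(self):
        grid = np.linspace(0, 1, 513)
        _, dens = epanechnikov_density([0.4, 0.6], bandwidth=0.05, grid=grid)
        np.testing.assert_allclose(dens, dens[::-1], atol=1e-12)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(-0.5, 1.5, 2001)
        _, dens = epanechnikov_density(rng.uniform(0, 1, 500), 0.05, grid=grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_mixture_mode_recovery(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(0.2, 0.04, 2500), rng.normal(0.8, 0.04, 2500)]
        )
        vals = np.clip(vals, 0, 1)
        grid, dens = epanechnikov_density(vals, 0.03)
        peaks = find_peaks(dens, grid)
        assert peaks.peak_u == pytest.approx(0.2, abs=0.02)
        assert peaks.peak_m == pytest.approx(0.8, abs=0.02)

    def test_agrees_with_sklearn_kde(self):
        """Dual route: sklearn's Epanechnikov KernelDensity as oracle."""
        from sklearn.neighbors import KernelDensity

        rng = np.random.default_rng(2)
        vals = rng.beta(2, 5, 300)
        grid = np.linspace(0.05, 0.95, 101)
        _, ours = epanechnikov_density(vals, 0.08, grid=grid)
        kde = KernelDensity(kernel="epanechnikov", bandwidth=0.08).fit(vals[:, None])
        theirs = np.exp(kde.score_samples(grid[:, None]))
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            epanechnikov_density([], 0.1)


class TestSilvermanBandwidth:
    def test_floor_applies_to_tight_data(self):
        assert silverman_bandwidth(np.full(100, 0.5) + 1e-9) == 0.02

    def test_scales_with_spread(self):
        rng = np.random.default_rng(3)
        narrow = silverman_bandwidth(rng.normal(0.5, 0.01, 1000))
        wide = silverman_bandwidth(rng.normal(0.5, 0.2, 1000))
        assert wide > narrow


class TestFindPeaks:
    def test_unimodal_density_is_degenerate(self):
        grid = np.linspace(0, 1, 101)
        dens = np.exp(-((grid - 0.5) ** 2) / 0.02)
        with pytest.raises(DegenerateDistributionError):
            find_peaks(dens, grid)

    def test_boundary_shift_does_not_move_clear_peaks(self):
        grid = np.linspace(0, 1, 201)
        dens = np.exp(-((grid - 0.1) ** 2) / 0.005) + np.exp(
            -((grid - 0.9) ** 2) / 0.005
        )
        p_default = find_peaks(dens, grid, boundary=0.5)
        p_shifted = find_peaks(dens, grid, boundary=0.3)
        assert p_default.peak_u == p_shifted.peak_u
        assert p_default.peak_m == p_shifted.peak_m

    def test_endpoints_count_as_modes(self):
        grid = np.linspace(0, 1, 101)
        dens = 1.0 - np.minimum(grid, 1 - grid)  # modes exactly at 0 and 1
        peaks = find_peaks(dens, grid)
        assert peaks.peak_u == 0.0
        assert peaks.peak_m == 1.0


class TestPbcTransform:
    PEAKS = PeakEstimate(0.2, 0.8, bandwidth=0.05)

    @pytest.mark.parametrize(
        "beta, expected",
        [(0.5, 0.5), (0.1, 0.0), (0.2, 0.0), (0.8, 1.0), (0.9, 1.0), (0.65, 0.75)],
    )
    def test_anchoring_and_clipping(self, beta, expected):
        assert pbc_transform(beta, self.PEAKS) == pytest.approx(expected)

    def test_missing_stays_missing(self):
        out = pbc_transform(np.array([0.5, np.nan]), self.PEAKS)
        assert np.isnan(out[1]) and not np.isnan(out[0])

    @given(
        beta=st.floats(0, 1),
        peak_u=st.floats(0.01, 0.45),
        delta=st.floats(0.1, 0.5),
    )
    @settings(max_examples=1000, derandomize=True)
    def test_scalar_oracle(self, beta, peak_u, delta):
        """Independent scalar re-derivation of the linear anchoring."""
        peak_m = min(peak_u + delta, 1.0)
        got = pbc_transform(beta, PeakEstimate(peak_u, peak_m, 0.05))
        expected = (beta - peak_u) / (peak_m - peak_u)
        expected = 0.0 if expected < 0 else 1.0 if expected > 1 else expected
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_within_stratum(self):
        rng = np.random.default_rng(4)
        betas = np.sort(rng.uniform(0, 1, 200))
        out = pbc_transform(betas, self.PEAKS)
        assert np.all(np.diff(out) >= 0)

    def test_invalid_peak_order_rejected_by_type(self):
        with pytest.raises(ValueError):
            PeakEstimate(0.8, 0.2, 0.05)


def _small_cohort(seed=0, n_samples=6, n_probes=2000, **truth_kw):
    truth = SimTruth(seed=seed, er_effect=0.0, **truth_kw)
    cohort = gen_beta_cohort(n_samples, n_probes, truth, seed=seed, n_promoter=0)
    return cohort, BetaMatrix(cohort.betas, cohort.probe_info)


class TestBetaMatrix:
    def test_requires_assay_type(self):
        values = pd.DataFrame({"s1": [0.5]}, index=["p1"])
        with pytest.raises(ValueError, match="assay_type"):
            BetaMatrix(values, pd.DataFrame(index=["p1"]))

    def test_rejects_out_of_range_betas(self):
        values = pd.DataFrame({"s1": [1.5]}, index=["p1"])
        info = pd.DataFrame({"assay_type": ["I"]}, index=["p1"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            BetaMatrix(values, info)

    def test_tsv_roundtrip(self, tmp_path):
        _, bm = _small_cohort()
        path = tmp_path / "b.tsv"
        bm.to_tsv(path)
        back = pd.read_csv(path, sep="\t", index_col="probe", na_values="NA")
        np.testing.assert_allclose(back.to_numpy(), bm.values.to_numpy(), atol=1e-9)


class TestPeakBasedCorrector:
    def test_corrected_modes_anchor_to_0_and_1(self):
        _, bm = _small_cohort()
        corrected, report = correct_cohort(bm)
        assert report["corrected"].all()
        for sample in corrected.values.columns:
            for assay in ("I", "II"):
                probes = bm.probe_info.index[bm.probe_info["assay_type"] == assay]
                vals = corrected.values.loc[probes, sample].dropna().to_numpy()
                grid, dens = epanechnikov_density(vals, 0.03)
                pk = find_peaks(dens, grid)
                assert pk.peak_u <= 0.03
                assert pk.peak_m >= 0.97

    def test_strata_never_mix_assay_types(self):
        _, bm = _small_cohort()
        corr = PeakBasedCorrector().fit(bm)
        rep = corr.report_
        assert len(rep) == bm.values.shape[1] * 2
        type1 = rep[rep["assay_type"] == "I"]
        type2 = rep[rep["assay_type"] == "II"]
        # the generator separates the per-type modes; fitted peaks must too
        assert type1["peak_u"].mean() < type2["peak_u"].mean()
        assert type1["peak_m"].mean() > type2["peak_m"].mean()

    def test_missingness_pattern_preserved(self):
        truth = SimTruth(seed=5, er_effect=0.0)
        cohort = gen_beta_cohort(6, 500, truth, seed=5, missing_fraction=0.1)
        bm = BetaMatrix(cohort.betas, cohort.probe_info)
        corrected, _ = correct_cohort(bm)
        np.testing.assert_array_equal(
            corrected.values.isna().to_numpy(), bm.values.isna().to_numpy()
        )
        finite = corrected.values.to_numpy()
        finite = finite[np.isfinite(finite)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0

    def test_all_missing_sample_passes_through_flagged(self):
        _, bm = _small_cohort(n_samples=4)
        values = bm.values.copy()
        values["s_empty"] = np.nan
        bm2 = BetaMatrix(values, bm.probe_info)
        corrected, report = correct_cohort(bm2)
        empty_rows = report[report["sample"] == "s_empty"]
        assert not empty_rows["corrected"].any()
        assert corrected.values["s_empty"].isna().all()

    def test_identical_samples_get_identical_corrections(self):
        _, bm = _small_cohort(n_samples=4)
        values = bm.values.copy()
        values["dup"] = values.iloc[:, 0]
        corrected, _ = correct_cohort(BetaMatrix(values, bm.probe_info))
        np.testing.assert_array_equal(
            corrected.values["dup"].to_numpy(), corrected.values.iloc[:, 0].to_numpy()
        )

    def test_near_idempotent_on_anchored_distribution(self):
        _, bm = _small_cohort()
        once, rep1 = correct_cohort(bm)
        twice, rep2 = correct_cohort(once)
        merged = rep2.merge(rep1, on=["sample", "assay_type"], suffixes=("_2", "_1"))
        # second-pass peaks sit within one bandwidth of the anchors 0 and 1
        assert (merged["peak_u_2"] <= merged["bandwidth_2"] + 1e-9).all()
        assert (merged["peak_m_2"] >= 1 - merged["bandwidth_2"] - 1e-9).all()

    def test_sklearn_param_interface(self):
        corr = PeakBasedCorrector(bandwidth=0.05, boundary=0.4)
        params = corr.get_params()
        assert params["bandwidth"] == 0.05 and params["boundary"] == 0.4
        cloned = sk_clone(corr)
        assert cloned.get_params() == params

    def test_transform_before_fit_raises(self):
        _, bm = _small_cohort(n_samples=4, n_probes=200)
        with pytest.raises(ValueError, match="not fitted"):
            PeakBasedCorrector().transform(bm)
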