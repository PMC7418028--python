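"""Session correction pipeline: background, non-linearity, transfer, drift, QC."""
import warnings

import numpy as np
import pandas as pd
import pytest

from dualclumped.isotopologue import BulkComposition, CycleIntensities, RawClumpedValues
from dualclumped.reduction import (
    DEFAULT_STANDARDS,
    BackgroundModel,
    DegenerateFitError,
    FitError,
    MissingStandardsError,
    ReductionConfig,
    ReductionError,
    ReplicateRecord,
    apply_pipeline,
    background_correct,
    fit_drift,
    fit_gas_nonlinearity,
    fit_scaling_factors,
    fit_transfer_function,
    qc_checks,
    summarize_replicates,
)
from dualclumped.synthetic import SimulationConfig, simulate_session


def _quiet(**overrides):
    base = dict(
        scaling_factors=(0.0, 0.0, 0.0), i47_5_mv=0.0,
        transfer_slope=(1.0, 1.0), transfer_intercept=(0.0, 0.0),
        drift_amplitude=(0.0, 0.0), nl_slope48=0.0,
        noise_sd_d47=0.0, noise_sd_d48=0.0, noise_sd_d49=0.0,
        noise_sd_d13c=0.0, noise_sd_d18o=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestBackgroundCorrect:
    def test_zero_factor_leaves_intensities(self):
        c = CycleIntensities(100.0, 1, 1, 100.0, 10.0, 1.0, i47_5=-2.0)
        assert background_correct(c, BackgroundModel()) is c

    def test_direct_subtraction_convention(self):
        """s = −1 with a −2 mV background adds back 2 mV."""
        c = CycleIntensities(1000.0, 1, 1, 100.0, 10.0, 1.0, i47_5=-2.0)
        out = background_correct(c, BackgroundModel(s47=-1.0))
        assert out.i47 == pytest.approx(102.0)
        assert out.i48 == 10.0 and out.i44 == 1000.0

    def test_fractional_factor(self):
        c = CycleIntensities(1000.0, 1, 1, 100.0, 10.0, 1.0, i47_5=-2.0)
        out = background_correct(c, BackgroundModel(s47=-0.988))
        assert out.i47 == pytest.approx(101.976)

    def test_missing_monitor_rejected(self):
        c = CycleIntensities(1000.0, 1, 1, 100.0, 10.0, 1.0, i47_5=None)
        with pytest.raises(ValueError, match="monitor"):
            background_correct(c, BackgroundModel(s47=-1.0))


class TestSummarize:
    @pytest.mark.parametrize(
        "sd, n, expected_2se",
        [
            (0.010, 78, 0.002),  # ETH 1 Δ47
            (0.036, 78, 0.008),  # ETH 1 Δ48
            (0.011, 71, 0.003),  # ETH 2 Δ47
            (0.029, 71, 0.007),  # ETH 2 Δ48
            (0.010, 74, 0.002),  # ETH 3 Δ47
            (0.042, 74, 0.010),  # ETH 3 Δ48
        ],
    )
    def test_two_se_arithmetic(self, sd, n, expected_2se):
        """2 SE = 2·SD/√n reproduces the long-term standard statistics."""
        z = np.resize([1.0, -1.0], n)
        z = z - z.mean()
        z = z / z.std(ddof=1)
        values = 0.5 + sd * z
        mean, sd_out, se2, n_out = summarize_replicates(values)
        assert sd_out == pytest.approx(sd, rel=1e-12)
        assert round(se2, 3) == expected_2se
        assert n_out == n

    def test_constant_vector(self):
        mean, sd, se2, n = summarize_replicates([0.6, 0.6, 0.6])
        assert sd == 0.0 and se2 == 0.0 and mean == 0.6

    def test_single_replicate_undefined(self):
        mean, sd, se2, n = summarize_replicates([0.6])
        assert n == 1 and np.isnan(sd) and np.isnan(se2)


class TestScalingFactors:
    def test_noise_free_recovery(self):
        """Injected scaling factors recovered within 1e-3 at zero noise."""
        cfg = _quiet(scaling_factors=(-0.988, -0.906, -0.648), i47_5_mv=-3.0)
        recs, _ = simulate_session(cfg, seed=11)
        eth = [r for r in recs if r.sample_id in ("ETH-1", "ETH-2")]
        bg = fit_scaling_factors(eth, wg_bulk=cfg.wg_bulk)
        assert bg.s47 == pytest.approx(-0.988, abs=1e-3)
        assert bg.s48 == pytest.approx(-0.906, abs=1e-3)
        assert bg.s49 == pytest.approx(-0.648, abs=1e-3)
        for m in (47, 48, 49):
            assert abs(bg.residual_slopes[m]) <= 1e-5

    def test_zero_background_degenerate(self):
        cfg = _quiet()
        recs, _ = simulate_session(cfg, seed=1)
        eth = [r for r in recs if r.sample_id in ("ETH-1", "ETH-2")]
        bg = fit_scaling_factors(eth, wg_bulk=cfg.wg_bulk)
        assert bg.s47 == 0.0 and bg.s48 == 0.0 and bg.s49 == 0.0
        assert all(bg.degenerate.values())

    def test_requires_both_standards(self):
        cfg = _quiet(i47_5_mv=-3.0, scaling_factors=(-1.0, -0.9, -0.6))
        recs, _ = simulate_session(cfg, seed=1)
        only_eth1 = [r for r in recs if r.sample_id == "ETH-1"]
        with pytest.raises(MissingStandardsError):
            fit_scaling_factors(only_eth1, wg_bulk=cfg.wg_bulk)


class TestTransferFunction:
    def test_identity_map(self):
        measured = {
            "ETH-1": DEFAULT_STANDARDS.accepted("ETH-1"),
            "ETH-3": DEFAULT_STANDARDS.accepted("ETH-3"),
        }
        tf = fit_transfer_function(measured)
        for mass in (47, 48):
            a, b = tf.channels[mass]
            assert a == pytest.approx(1.0, abs=1e-12)
            assert b == pytest.approx(0.0, abs=1e-12)

    def test_compression_algebra(self):
        """measured = 0.9·accepted − 0.05 inverts to slope 1/0.9, intercept 0.05/0.9."""
        measured = {}
        for name in ("ETH-1", "ETH-3"):
            acc = DEFAULT_STANDARDS.accepted(name)
            measured[name] = (0.9 * acc[0] - 0.05, 0.9 * acc[1] - 0.05)
        tf = fit_transfer_function(measured)
        for mass in (47, 48):
            a, b = tf.channels[mass]
            assert a == pytest.approx(1.0 / 0.9, rel=1e-12)
            assert b == pytest.approx(0.05 / 0.9, rel=1e-12)

    def test_fitted_function_reproduces_standards(self):
        measured = {
            "ETH-1": (0.15, 0.10),
            "ETH-3": (0.52, 0.24),
        }
        tf = fit_transfer_function(measured)
        for name, (m47, m48) in measured.items():
            acc = DEFAULT_STANDARDS.accepted(name)
            assert tf.apply(47, m47) == pytest.approx(acc[0], abs=1e-12)
            assert tf.apply(48, m48) == pytest.approx(acc[1], abs=1e-12)

    def test_rank_deficiency(self):
        """Two standards with identical accepted values cannot fix a line."""
        with pytest.raises(FitError, match="rank deficient"):
            fit_transfer_function({"ETH-1": (0.15, 0.1), "ETH-2": (0.18, 0.12)})

    def test_too_few_standards(self):
        with pytest.raises(MissingStandardsError):
            fit_transfer_function({"ETH-3": (0.5, 0.2)})


class TestDrift:
    def test_zero_residuals_zero_function(self):
        t = np.linspace(0, 500, 20)
        model = fit_drift({47: list(zip(t, np.zeros_like(t)))}, window_h=48.0)
        assert np.allclose(model.correction(47, t), 0.0)

    def test_linear_drift_round_trip(self):
        """A noise-free linear drift of 0.008‰ over the session is recovered
        to 1e-6 at every timestamp, including the session edges."""
        t = np.linspace(0, 720, 60)
        drift = 0.008 * (t / 720 - 0.5)
        model = fit_drift({47: list(zip(t, drift))}, window_h=48.0)
        probe = np.linspace(0, 720, 301)
        expected = 0.008 * (probe / 720 - 0.5)
        assert np.max(np.abs(model.correction(47, probe) - expected)) < 1e-6

    def test_wide_window_constant_model(self):
        t = np.linspace(0, 30, 8)
        r = 0.001 * np.ones_like(t)
        with pytest.warns(UserWarning, match="constant"):
            model = fit_drift({47: list(zip(t, r))}, window_h=100.0)
        assert np.allclose(model.correction(47, [0.0, 15.0, 30.0]), 0.001)

    def test_too_few_replicates(self):
        with pytest.raises(FitError, match="≥ 5"):
            fit_drift({47: [(0.0, 0.0), (1.0, 0.0)]}, window_h=10.0)

    def test_large_drift_flagged(self):
        t = np.linspace(0, 720, 40)
        drift = 0.05 * (t / 720 - 0.5)  # exceeds the 0.010‰ advisory bound
        with pytest.warns(UserWarning, match="exceeds"):
            model = fit_drift({47: list(zip(t, drift))}, window_h=48.0)
        assert model.flagged[47] is True


class TestGasNonlinearity:
    def _gas_session(self, seed=0, **overrides):
        cfg = _quiet(
            cycle_data=False, n_gas_25c=15, n_gas_1000c=15,
            nl_slope48=overrides.pop("nl_slope48", -0.0040),
            noise_sd_d47=overrides.pop("noise_sd_d47", 0.010),
            noise_sd_d48=overrides.pop("noise_sd_d48", 0.036),
            noise_sd_d49=0.1,
            **overrides,
        )
        recs, _ = simulate_session(cfg, seed=seed)
        return cfg, [r for r in recs if "gas" in r.role]

    def test_injected_slope_recovered_within_se(self):
        cfg, gases = self._gas_session(seed=4)
        fit = fit_gas_nonlinearity(gases, wg_bulk=cfg.wg_bulk)
        slope, se = fit.slopes[48]
        assert abs(slope - (-0.0040)) <= 2 * se

    def test_zero_slope_flat_flag(self):
        cfg, gases = self._gas_session(seed=4, nl_slope48=0.0)
        fit = fit_gas_nonlinearity(gases, wg_bulk=cfg.wg_bulk)
        slope, se = fit.slopes[48]
        assert abs(slope) <= 2 * se
        assert not fit.needs_correction[48]

    def test_delta47_channel_flat(self):
        cfg, gases = self._gas_session(seed=6)
        fit = fit_gas_nonlinearity(gases, wg_bulk=cfg.wg_bulk)
        assert not fit.needs_correction[47]

    def test_incompatible_families_error(self):
        """Families whose injected slopes differ wildly are refused."""
        cfg, gases = self._gas_session(seed=2, noise_sd_d47=0.002, noise_sd_d48=0.004)
        # impose an extra, family-dependent slope on the 25 °C family only
        for rec in gases:
            if rec.role == "equilibrated_gas_25C":
                raw = rec.raw
                rec.raw = RawClumpedValues(
                    d45=raw.d45, d46=raw.d46, d47=raw.d47, d48=raw.d48, d49=raw.d49,
                    D47_raw=raw.D47_raw,
                    D48_raw=raw.D48_raw + 0.05 * raw.d48,
                    D49_raw=raw.D49_raw,
                    d13c=raw.d13c, d18o=raw.d18o,
                )
        with pytest.raises(FitError, match="differ in non-linearity slope"):
            fit_gas_nonlinearity(gases, wg_bulk=cfg.wg_bulk)

    def test_single_family_warns(self):
        cfg, gases = self._gas_session(seed=3)
        only25 = [r for r in gases if r.role == "equilibrated_gas_25C"]
        with pytest.warns(UserWarning, match="one gas family"):
            fit_gas_nonlinearity(only25, wg_bulk=cfg.wg_bulk)


class TestPipeline:
    def test_zero_distortion_identity(self, quiet_config):
        recs, manifest = simulate_session(quiet_config, seed=1)
        result = apply_pipeline(recs)
        for _, row in result.samples.iterrows():
            t47, t48 = manifest.truths[row.sample_id]
            assert row.d47 == pytest.approx(t47, abs=1e-9)
            assert row.d48 == pytest.approx(t48, abs=1e-9)
        assert (result.samples["se47_2"].dropna() >= 0).all()

    def test_distorted_noise_free_recovery(self, distorted_quiet_config):
        """Background + compression, no noise: truths recovered to 1e-6 and
        the injected transfer function is reproduced."""
        cfg = distorted_quiet_config
        recs, manifest = simulate_session(cfg, seed=2)
        result = apply_pipeline(recs)
        for _, row in result.samples.iterrows():
            t47, t48 = manifest.truths[row.sample_id]
            assert row.d47 == pytest.approx(t47, abs=1e-6)
            assert row.d48 == pytest.approx(t48, abs=1e-6)
        a47, b47 = result.transfer.channels[47]
        assert a47 == pytest.approx(cfg.transfer_slope[0], abs=1e-6)
        assert b47 == pytest.approx(cfg.transfer_intercept[0], abs=1e-6)

    def test_standards_round_trip_to_accepted(self, quiet_config):
        """Anchor standards processed as unknowns return their accepted
        values (exactly at zero noise)."""
        recs, _ = simulate_session(quiet_config, seed=3)
        result = apply_pipeline(recs)
        std = result.samples.set_index("sample_id")
        for name in ("ETH-1", "ETH-2", "ETH-3"):
            acc = DEFAULT_STANDARDS.accepted(name)
            assert std.loc[name, "d47"] == pytest.approx(acc[0], abs=1e-9)
            assert std.loc[name, "d48"] == pytest.approx(acc[1], abs=1e-9)

    def test_two_se_contract(self):
        """Reported 2 SE equals 2·SD/√n exactly for every sample."""
        recs, _ = simulate_session(SimulationConfig(), seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = apply_pipeline(recs)
        for _, row in result.samples.iterrows():
            assert row.se47_2 == pytest.approx(2 * row.sd47 / np.sqrt(row.n), rel=1e-12)

    def test_correction_order_matters(self, distorted_quiet_config):
        """Skipping the background step (i.e. permuting the fixed order)
        changes the outputs of a distorted session."""
        recs, _ = simulate_session(distorted_quiet_config, seed=4)
        full = apply_pipeline(recs)
        no_bg = apply_pipeline(
            recs, config=ReductionConfig(background=BackgroundModel())
        )
        merged = full.samples.merge(no_bg.samples, on="sample_id", suffixes=("_a", "_b"))
        assert (np.abs(merged["d48_a"] - merged["d48_b"]) > 1e-4).any()

    def test_missing_standards_error(self, quiet_config):
        recs, _ = simulate_session(quiet_config, seed=1)
        unknowns_only = [r for r in recs if r.role == "unknown"]
        with pytest.raises(MissingStandardsError):
            apply_pipeline(unknowns_only)

    def test_coverage_matches_oracle(self):
        """Truth-in-2SE coverage of unknowns under the default noisy
        conditions agrees with an independent Monte-Carlo oracle.

        The oracle draws i.i.d. normal replicates (n = 8) plus a shared
        standardisation offset (σ/√20 from the 20-replicate standards) and
        evaluates P(|mean error| ≤ 2·SD_est/√n) directly; nominal coverage
        is ≈ 0.86, not 95%, because 2·SD_est/√n at small n is narrower than
        a true 95% interval.
        """
        rng = np.random.default_rng(2024)
        n_rep, n_std = 8, 20
        reps = rng.normal(0.0, 1.0, (60_000, n_rep))
        shared = rng.normal(0.0, 1.0 / np.sqrt(n_std), 60_000)
        err = reps.mean(axis=1) + shared
        se2 = 2.0 * reps.std(axis=1, ddof=1) / np.sqrt(n_rep)
        oracle = float(np.mean(np.abs(err) <= se2))

        hits = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(40):
                recs, manifest = simulate_session(SimulationConfig(), seed=seed)
                result = apply_pipeline(recs)
                for _, row in result.samples.iterrows():
                    if row.role != "unknown":
                        continue
                    t47, t48 = manifest.truths[row.sample_id]
                    hits.append(abs(row.d47 - t47) <= row.se47_2)
                    hits.append(abs(row.d48 - t48) <= row.se48_2)
        coverage = float(np.mean(hits))
        binom_se = np.sqrt(oracle * (1 - oracle) / len(hits))
        assert abs(coverage - oracle) <= 4 * binom_se + 0.02


class TestQC:
    def _frame(self, d49_values, roles=None, d48=None):
        n = len(d49_values)
        return pd.DataFrame(
            {
                "replicate_id": [f"r{i}" for i in range(n)],
                "sample_id": ["S"] * n,
                "role": roles or ["unknown"] * n,
                "D48_raw": d48 if d48 is not None else np.linspace(0.1, 0.2, n),
                "D49_raw": d49_values,
            }
        )

    def test_d49_inside_range_passes(self):
        df = self._frame([0.1, 0.2, 0.15])
        res = qc_checks(df, gas_d49_range=(-1.0, 1.0))
        assert not res.replicate_d49_flag.any()

    def test_d49_outside_range_flagged(self):
        df = self._frame([0.1, 5.0, 0.15])
        res = qc_checks(df, gas_d49_range=(-1.0, 1.0))
        assert res.replicate_d49_flag.tolist() == [False, True, False]

    def test_gas_range_from_gas_replicates(self):
        df = self._frame(
            [0.0, 1.0, 0.5, 3.0],
            roles=["equilibrated_gas_25C", "equilibrated_gas_1000C", "unknown", "unknown"],
        )
        res = qc_checks(df)
        assert res.gas_d49_range == (0.0, 1.0)
        assert res.replicate_d49_flag.tolist() == [False, False, False, True]

    def test_correlation_type_i_error_rate(self):
        """Uncorrelated Δ48/Δ49 noise triggers the correlation flag at the
        nominal ≤ 5% rate."""
        rng = np.random.default_rng(99)
        flags = 0
        trials = 400
        for _ in range(trials):
            df = self._frame(
                rng.normal(0, 0.2, 10), d48=rng.normal(0.15, 0.04, 10)
            )
            res = qc_checks(df, gas_d49_range=(-10, 10))
            flags += res.sample_corr["S"][2]
        rate = flags / trials
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)

    def test_shapiro_on_standards(self, quiet_config):
        recs, _ = simulate_session(quiet_config, seed=1)
        result = apply_pipeline(recs)
        assert set(result.qc.standard_normality) == {"ETH-1", "ETH-2", "ETH-3"}

    def test_all_replicates_flagged_is_error(self, quiet_config):
        recs, _ = simulate_session(quiet_config, seed=1)
        cfg = ReductionConfig(gas_d49_range=(100.0, 101.0))  # nothing passes
        with pytest.raises(ReductionError, match="failed the Δ49 QC"):
            apply_pipeline(recs, config=cfg)
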