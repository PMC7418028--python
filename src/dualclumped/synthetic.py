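"""Forward-model generator of measurement sessions with known ground truth.

The generator is the exact inverse of the correction chain: per replicate it
starts from the true CDES90 (Δ47, Δ48), adds the temporal drift, maps the
result back through the inverse transfer function (scale compression),
builds per-cycle beam intensities with the isotopologue forward model, and
finally injects the negative m/z 47.5 background at the intensity level.
Gaussian noise is applied at the replicate δ/Δ level (per-cycle shot noise
is optional and off by default — replicate-level noise is what the
correction pipeline sees and is much cheaper).

Default condition set: standards interleaved with unknowns over a
multi-week session, replicate scatter of 0.010‰ (Δ47) and 0.036‰ (Δ48)
matching the long-term reference-material statistics, background scaling
factors (−0.988, −0.906, −0.648), and samples measured in 5–10 replicates.
Everything injected is recorded in a :class:`TruthManifest` so parameter
recovery can be asserted exactly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .equilibrium import EquilibriumCalibration, Temperature, default_calibration
from .isotopologue import (
    BRAND_CONSTANTS,
    BulkComposition,
    CycleIntensities,
    DEFAULT_GAINS,
    IsotopeConstants,
    RawClumpedValues,
    intensities_from_composition,
    stochastic_ratios,
)
from .kinetics import ClumpedPair, KineticSlope
from .reduction import GAS_ROLES, GasTheory, ReplicateRecord

__all__ = [
    "SampleTruth",
    "SimulationConfig",
    "TruthManifest",
    "simulate_session",
    "simulate_kinetic_sample",
    "default_config",
]


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated sample.

    Either (``d47``, ``d48``) are given directly, or a growth temperature
    plus a kinetic displacement along a slope define them through the
    calibration.
    """

    sample_id: str
    d13c: float = 0.0
    d18o: float = 0.0
    d47: float | None = None
    d48: float | None = None
    d49: float = 0.0
    growth_temperature_c: float | None = None
    kinetic_slope: float | None = None
    displacement: float = 0.0
    replicates: int = 8
    role: str = "unknown"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be ≥ 1")
        if self.d47 is None and self.growth_temperature_c is None:
            raise ValueError(
                f"sample {self.sample_id!r}: give (d47, d48) or a growth temperature"
            )

    def resolve(self, cal: EquilibriumCalibration) -> tuple[float, float]:
        """True (Δ47, Δ48) of the sample."""
        if self.d47 is not None and self.d48 is not None:
            return (self.d47, self.d48)
        t = Temperature.from_celsius(self.growth_temperature_c)
        pair = simulate_kinetic_sample(
            t,
            KineticSlope(self.kinetic_slope if self.kinetic_slope is not None else -1.0),
            self.displacement,
            cal,
        )
        return (pair.d47, pair.d48)


def _default_standards() -> tuple[SampleTruth, ...]:
    # truths follow the joint ETH 1+2 accepted values; bulk compositions are
    # spread widely so the Δ-vs-δ scaling-factor fit is well conditioned
    return (
        SampleTruth("ETH-1", d13c=2.0, d18o=6.5, d47=0.212, d48=0.140,
                    replicates=20, role="anchor_standard"),
        SampleTruth("ETH-2", d13c=-10.2, d18o=-10.5, d47=0.212, d48=0.140,
                    replicates=20, role="anchor_standard"),
        SampleTruth("ETH-3", d13c=1.7, d18o=6.9, d47=0.615, d48=0.299,
                    replicates=20, role="anchor_standard"),
    )


def _default_unknowns() -> tuple[SampleTruth, ...]:
    return (
        SampleTruth("EQ-33.7C", d13c=0.5, d18o=4.0,
                    growth_temperature_c=33.7, kinetic_slope=-1.0,
                    displacement=0.0, replicates=8),
        SampleTruth("EQ-5C", d13c=-6.0, d18o=2.0,
                    growth_temperature_c=5.0, kinetic_slope=-1.0,
                    displacement=0.0, replicates=8),
        SampleTruth("KIN-DEGAS", d13c=-5.0, d18o=-2.0,
                    growth_temperature_c=30.7, kinetic_slope=-1.0,
                    displacement=0.025, replicates=8),
        SampleTruth("KIN-ABSORB", d13c=-2.5, d18o=-4.5,
                    growth_temperature_c=29.3, kinetic_slope=-0.6,
                    displacement=-0.09, replicates=8),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Layout, truths, injected distortions, and noise levels of a session."""

    standards: tuple[SampleTruth, ...] = field(default_factory=_default_standards)
    unknowns: tuple[SampleTruth, ...] = field(default_factory=_default_unknowns)
    n_gas_25c: int = 0
    n_gas_1000c: int = 0
    session_id: str = "synthetic-session"
    session_span_h: float = 720.0
    wg_bulk: BulkComposition = field(default_factory=lambda: BulkComposition(-4.6, -5.0))
    constants: IsotopeConstants = BRAND_CONSTANTS
    gas_theory: GasTheory = field(default_factory=GasTheory)

    # distortions
    scaling_factors: tuple[float, float, float] = (-0.988, -0.906, -0.648)
    i47_5_mv: float = -3.0
    transfer_slope: tuple[float, float] = (1.10, 1.15)
    transfer_intercept: tuple[float, float] = (0.15, 0.05)
    drift_amplitude: tuple[float, float] = (0.008, 0.025)
    nl_slope48: float = -0.0040  # Δ-level injection when cycle data are off

    # noise (1 SD per replicate)
    noise_sd_d47: float = 0.010
    noise_sd_d48: float = 0.036
    noise_sd_d49: float = 0.20
    noise_sd_d13c: float = 0.01
    noise_sd_d18o: float = 0.02

    # instrument layer
    cycle_data: bool = True
    n_cycles: int = 10
    i44_mv: float = 16000.0
    i44_jitter: float = 0.02
    gains: tuple[float, float, float, float, float] = DEFAULT_GAINS
    cycle_noise_mv: float = 0.0  # optional per-cycle shot-noise mode

    def __post_init__(self) -> None:
        for name in ("noise_sd_d47", "noise_sd_d48", "noise_sd_d49",
                     "noise_sd_d13c", "noise_sd_d18o"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


def default_config(**overrides) -> SimulationConfig:
    """The default session conditions, optionally overridden field-by-field."""
    return dataclasses.replace(SimulationConfig(), **overrides)


@dataclass
class TruthManifest:
    """Every injected parameter and per-sample truth of a simulated session."""

    seed: int
    session_id: str
    truths: dict[str, tuple[float, float]]
    scaling_factors: tuple[float, float, float]
    i47_5_mv: float
    transfer_slope: tuple[float, float]
    transfer_intercept: tuple[float, float]
    drift_amplitude: tuple[float, float]
    nl_slope48: float
    noise_sd: dict[str, float]
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def simulate_kinetic_sample(
    growth_temperature: Temperature | float,
    slope: KineticSlope,
    displacement: float,
    cal: EquilibriumCalibration | None = None,
) -> ClumpedPair:
    """Equilibrium pair at the growth temperature displaced along a kinetic
    slope: (Δ48 + d, Δ47 + slope·d)."""
    cal = cal or default_calibration()
    d47 = cal.delta47(growth_temperature) + slope.value * displacement
    d48 = cal.delta48(growth_temperature) + displacement
    return ClumpedPair(d47=d47, d48=d48, sample_id="kinetic")


def _drift_true(t: float, span: float, amplitude: float) -> float:
    """Linear ramp, zero-mean over the session."""
    return amplitude * (t / span - 0.5)


def _delta_small(bulk: BulkComposition, wg_bulk: BulkComposition,
                 const: IsotopeConstants, mass: int, big_delta: float) -> float:
    """δm of a gas vs the (stochastic) working gas, given its Δm."""
    st_s = stochastic_ratios(bulk, const)
    st_w = stochastic_ratios(wg_bulk, const)
    return (st_s.by_mass(mass) * (1.0 + big_delta / 1000.0) / st_w.by_mass(mass) - 1.0) * 1000.0


def simulate_session(
    config: SimulationConfig | None = None,
    seed: int = 0,
    cal: EquilibriumCalibration | None = None,
) -> tuple[list[ReplicateRecord], TruthManifest]:
    """Generate one session of replicate records plus its truth manifest.

    Deterministic for a fixed seed: the same (config, seed) pair always
    yields identical records.
    """
    cfg = config or SimulationConfig()
    cal = cal or default_calibration()
    rng = np.random.default_rng(seed)
    const = cfg.constants

    # roster: round-robin over samples so standards interleave with unknowns
    entries: list[tuple[SampleTruth, str]] = []
    samples = list(cfg.standards) + list(cfg.unknowns)
    gas_truths: list[SampleTruth] = []
    for fam, n, role in (("GAS-25C", cfg.n_gas_25c, GAS_ROLES[0]),
                         ("GAS-1000C", cfg.n_gas_1000c, GAS_ROLES[1])):
        if n > 0:
            d47t, d48t = cfg.gas_theory.pair(role)
            gas_truths.append(
                SampleTruth(fam, d47=d47t, d48=d48t, replicates=n, role=role)
            )
    roster_samples = samples + gas_truths
    max_reps = max(s.replicates for s in roster_samples)
    for i in range(max_reps):
        for s in roster_samples:
            if i < s.replicates:
                entries.append((s, f"{s.sample_id}-{i + 1:02d}"))

    n_total = len(entries)
    timestamps = np.linspace(0.0, cfg.session_span_h, n_total)
    timestamps = timestamps + rng.uniform(-0.5, 0.5, n_total) * (
        cfg.session_span_h / max(n_total, 2) * 0.5
    )
    timestamps = np.clip(timestamps, 0.0, cfg.session_span_h)

    a47, a48 = cfg.transfer_slope
    b47, b48 = cfg.transfer_intercept
    s47, s48, s49 = cfg.scaling_factors

    truths: dict[str, tuple[float, float]] = {}
    records: list[ReplicateRecord] = []
    for (truth, rep_id), t in zip(entries, timestamps):
        is_gas = truth.role in GAS_ROLES
        d47_true, d48_true = truth.resolve(cal)
        truths.setdefault(truth.sample_id, (d47_true, d48_true))

        # gas bulk compositions span a wide δ range (varied equilibration
        # aliquots); carbonates keep their fixed bulk
        if is_gas:
            bulk = BulkComposition(
                d13c=float(rng.uniform(-25.0, 5.0)),
                d18o=float(rng.uniform(-12.0, 10.0)),
            )
        else:
            bulk = BulkComposition(truth.d13c, truth.d18o)

        # forward chain: truth -> drift -> inverse transfer -> noise
        d47_c = d47_true
        d48_c = d48_true
        if not is_gas:  # drift lives in the acid reaction environment
            d47_c += _drift_true(t, cfg.session_span_h, cfg.drift_amplitude[0])
            d48_c += _drift_true(t, cfg.session_span_h, cfg.drift_amplitude[1])
        d47_rawnl = (d47_c - b47) / a47
        d48_rawnl = (d48_c - b48) / a48
        d49_rawnl = truth.d49

        d47_rawnl += rng.normal(0.0, cfg.noise_sd_d47)
        d48_rawnl += rng.normal(0.0, cfg.noise_sd_d48)
        d49_rawnl += rng.normal(0.0, cfg.noise_sd_d49)
        bulk = BulkComposition(
            bulk.d13c + rng.normal(0.0, cfg.noise_sd_d13c),
            bulk.d18o + rng.normal(0.0, cfg.noise_sd_d18o),
        )

        if cfg.cycle_data and not is_gas:
            sample_cycles, wg_cycles = [], []
            for _ in range(cfg.n_cycles):
                i44 = cfg.i44_mv * (1.0 + rng.uniform(-cfg.i44_jitter, cfg.i44_jitter))
                i475 = cfg.i47_5_mv * (i44 / cfg.i44_mv)
                sc = intensities_from_composition(
                    bulk, D47=d47_rawnl, D48=d48_rawnl, D49=d49_rawnl,
                    i44=i44, gains=cfg.gains, i47_5=i475, side="sample", const=const,
                )
                wc = intensities_from_composition(
                    cfg.wg_bulk, i44=i44, gains=cfg.gains, i47_5=i475,
                    side="working_gas", const=const,
                )
                # inject the negative background: measured = clean − s·i47.5
                def _bg(c: CycleIntensities) -> CycleIntensities:
                    noise = (
                        rng.normal(0.0, cfg.cycle_noise_mv, 3)
                        if cfg.cycle_noise_mv > 0
                        else np.zeros(3)
                    )
                    return dataclasses.replace(
                        c,
                        i47=c.i47 - s47 * i475 + noise[0],
                        i48=c.i48 - s48 * i475 + noise[1],
                        i49=c.i49 - s49 * i475 + noise[2],
                    )

                sample_cycles.append(_bg(sc))
                wg_cycles.append(_bg(wc))
            records.append(
                ReplicateRecord(
                    replicate_id=rep_id,
                    sample_id=truth.sample_id,
                    role=truth.role,
                    timestamp_h=float(t),
                    session_id=cfg.session_id,
                    sample_cycles=sample_cycles,
                    wg_cycles=wg_cycles,
                )
            )
        else:
            # Δ-level record; the non-linearity is injected directly in
            # Δ-vs-δ space (gas sessions and fast pipeline tests)
            deltas = {
                m: _delta_small(bulk, cfg.wg_bulk, const, m, bd)
                for m, bd in ((45, 0.0), (46, 0.0), (47, d47_rawnl),
                              (48, d48_rawnl), (49, d49_rawnl))
            }
            d48_rawnl_obs = d48_rawnl + cfg.nl_slope48 * deltas[48]
            raw = RawClumpedValues(
                d45=deltas[45], d46=deltas[46], d47=deltas[47],
                d48=deltas[48], d49=deltas[49],
                D47_raw=d47_rawnl, D48_raw=d48_rawnl_obs, D49_raw=d49_rawnl,
                d13c=bulk.d13c, d18o=bulk.d18o,
            )
            records.append(
                ReplicateRecord(
                    replicate_id=rep_id,
                    sample_id=truth.sample_id,
                    role=truth.role,
                    timestamp_h=float(t),
                    session_id=cfg.session_id,
                    raw=raw,
                )
            )

    manifest = TruthManifest(
        seed=seed,
        session_id=cfg.session_id,
        truths=truths,
        scaling_factors=cfg.scaling_factors,
        i47_5_mv=cfg.i47_5_mv,
        transfer_slope=cfg.transfer_slope,
        transfer_intercept=cfg.transfer_intercept,
        drift_amplitude=cfg.drift_amplitude,
        nl_slope48=cfg.nl_slope48,
        noise_sd={
            "d47": cfg.noise_sd_d47,
            "d48": cfg.noise_sd_d48,
            "d49": cfg.noise_sd_d49,
        },
        config={
            "session_span_h": cfg.session_span_h,
            "n_replicates": n_total,
            "cycle_data": cfg.cycle_data,
            "mode_hint": "carbonate" if cfg.n_gas_25c + cfg.n_gas_1000c == 0 else "gas",
        },
    )
    return records, manifest
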