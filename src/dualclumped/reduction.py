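"""Session-level standards-based correction pipeline.

A measurement session is a sequence of replicate analyses: carbonate
reference materials (ETH 1/2/3), optional CO2 gases equilibrated at 25 °C
or 1000 °C, and unknowns.  Correction proceeds in a fixed order:

1. **Non-linearity.**  A negative secondary-electron background under the
   m/z 47–49 cups, monitored on the half-mass m/z 47.5 cup, produces
   spurious slopes of Δ(raw) against δ.  In *carbonate* mode the background
   is removed at the intensity level: per channel, a scaling factor s is
   root-found such that the OLS slope of Δ(raw) vs δ across the ETH 1 + 2
   replicates (which share identical accepted Δ values but differ widely in
   bulk composition) vanishes after applying
   ``i_corrected = i + s·i47_5``.  In *gas* mode the slope is estimated from
   the two equilibrated-gas families and subtracted in Δ/δ space.
2. **Scale compression.**  An empirical per-channel linear transfer
   function maps non-linearity-corrected Δ(raw) onto the CDES90 scale,
   fitted from the accepted values of the carbonate standards (carbonate
   mode) or the theoretical gas equilibrium values (gas mode).
3. **Temporal drift.**  Residuals of the standards against their accepted
   values, as a function of session time, are smoothed by windowed means
   joined piecewise-linearly (linear extrapolation at the session edges)
   and subtracted from every replicate.

Replicates are then aggregated per sample (mean, SD with n−1 denominator,
2 SE = 2·SD/√n) with advisory quality control: Δ49(raw) inside the
equilibrated-gas range (contamination proxy), absence of Δ48–Δ49
correlation, and Shapiro–Wilk normality of the standard populations.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .isotopologue import (
    BRAND_CONSTANTS,
    BulkComposition,
    CycleIntensities,
    IsotopeConstants,
    RawClumpedValues,
    bracket_working_gas,
    raw_deltas,
    solve_bulk_composition,
    stochastic_ratios,
)

__all__ = [
    "ReplicateRecord",
    "StandardValue",
    "AcceptedStandards",
    "DEFAULT_STANDARDS",
    "GasTheory",
    "BackgroundModel",
    "NonlinearityFit",
    "TransferFunction",
    "DriftModel",
    "SessionResult",
    "ReductionConfig",
    "ReductionError",
    "MissingStandardsError",
    "DegenerateFitError",
    "FitError",
    "background_correct",
    "reduce_replicate",
    "fit_scaling_factors",
    "fit_gas_nonlinearity",
    "fit_transfer_function",
    "fit_drift",
    "apply_pipeline",
    "summarize_replicates",
    "qc_checks",
]

GAS_ROLES = ("equilibrated_gas_25C", "equilibrated_gas_1000C")
ROLES = ("anchor_standard", "check_standard", "unknown") + GAS_ROLES

#: Drift-correction magnitudes beyond which a session is flagged (‰).
DRIFT_FLAG_LIMITS = {47: 0.010, 48: 0.030}


class ReductionError(RuntimeError):
    """Base class for correction-pipeline failures."""


class MissingStandardsError(ReductionError):
    """The session lacks the standards a correction step requires."""


class FitError(ReductionError):
    """A correction fit could not be established."""


class DegenerateFitError(FitError):
    """The fit is degenerate (e.g. no background signal to scale)."""


@dataclass
class ReplicateRecord:
    """One replicate analysis: either raw Δ/δ values, per-cycle beam
    intensities, or both."""

    replicate_id: str
    sample_id: str
    role: str
    timestamp_h: float
    session_id: str = ""
    raw: RawClumpedValues | None = None
    sample_cycles: list[CycleIntensities] | None = None
    wg_cycles: list[CycleIntensities] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.raw is None and self.sample_cycles is None:
            raise ValueError(
                f"replicate {self.replicate_id!r} carries neither raw values nor cycles"
            )

    @property
    def has_cycles(self) -> bool:
        return self.sample_cycles is not None and self.wg_cycles is not None


@dataclass(frozen=True)
class StandardValue:
    d47: float
    se47_2: float
    sd47: float
    d48: float
    se48_2: float
    sd48: float
    n: int


def _norm_name(name: str) -> str:
    return name.strip().upper().replace(" ", "-").replace("_", "-")


@dataclass(frozen=True)
class AcceptedStandards:
    """Accepted long-term CDES90 values of the carbonate reference materials.

    ETH 1 and ETH 2 were both equilibrated at 600 °C and are treated as
    sharing identical Δ values; when ``joint_eth12`` is set their joint
    mean replaces the per-standard entries in every correction fit.
    """

    table: dict[str, StandardValue]
    joint_eth12: bool = True
    joint_eth12_values: tuple[float, float] = (0.212, 0.140)

    def __post_init__(self) -> None:
        for name, sv in self.table.items():
            if sv.se47_2 < 0 or sv.se48_2 < 0 or sv.sd47 < 0 or sv.sd48 < 0:
                raise ValueError(f"negative uncertainty for standard {name!r}")

    def names(self) -> list[str]:
        return list(self.table)

    def __contains__(self, name: str) -> bool:
        return _norm_name(name) in self.table

    def accepted(self, name: str) -> tuple[float, float]:
        """(Δ47, Δ48) used for correction, honouring the ETH 1+2 joint rule."""
        key = _norm_name(name)
        if key not in self.table:
            raise KeyError(f"no accepted values for standard {name!r}")
        if self.joint_eth12 and key in ("ETH-1", "ETH-2"):
            return self.joint_eth12_values
        sv = self.table[key]
        return (sv.d47, sv.d48)


DEFAULT_STANDARDS = AcceptedStandards(
    table={
        "ETH-1": StandardValue(0.212, 0.002, 0.010, 0.142, 0.008, 0.036, 78),
        "ETH-2": StandardValue(0.212, 0.003, 0.011, 0.138, 0.007, 0.029, 71),
        "ETH-3": StandardValue(0.615, 0.002, 0.010, 0.299, 0.010, 0.042, 74),
    }
)


@dataclass(frozen=True)
class GasTheory:
    """Theoretical equilibrium Δ47/Δ48 of CO2 at the gas-equilibration
    temperatures (CDES90; configurable, not printed constants)."""

    d47_25c: float = 0.920
    d47_1000c: float = 0.027
    d48_25c: float = 0.345
    d48_1000c: float = 0.000

    def pair(self, role: str) -> tuple[float, float]:
        if role == "equilibrated_gas_25C":
            return (self.d47_25c, self.d48_25c)
        if role == "equilibrated_gas_1000C":
            return (self.d47_1000c, self.d48_1000c)
        raise ValueError(f"not a gas role: {role!r}")


@dataclass
class BackgroundModel:
    """m/z 47.5 background scaling factors per channel."""

    s47: float = 0.0
    s48: float = 0.0
    s49: float = 0.0
    session_id: str = ""
    degenerate: dict[int, bool] = field(default_factory=dict)
    residual_slopes: dict[int, float] = field(default_factory=dict)

    def factor(self, mass: int) -> float:
        return {47: self.s47, 48: self.s48, 49: self.s49}[mass]

    @property
    def is_zero(self) -> bool:
        return self.s47 == 0.0 and self.s48 == 0.0 and self.s49 == 0.0


@dataclass
class NonlinearityFit:
    """Per-channel slope of Δ(raw) vs δ estimated from equilibrated gases."""

    slopes: dict[int, tuple[float, float]]  # mass -> (slope, SE)
    needs_correction: dict[int, bool]
    family_fits: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)
    family_intercepts: dict[str, dict[int, float]] = field(default_factory=dict)
    source: str = "equilibrated_gases"


@dataclass
class TransferFunction:
    """Linear map per channel from corrected raw Δ to the CDES90 scale."""

    channels: dict[int, tuple[float, float]]  # mass -> (slope, intercept)

    def __post_init__(self) -> None:
        for mass, (a, _) in self.channels.items():
            if a <= 0:
                raise FitError(f"transfer-function slope for Δ{mass} must be > 0, got {a}")

    def apply(self, mass: int, values):
        a, b = self.channels[mass]
        return a * np.asarray(values, dtype=float) + b


@dataclass
class DriftChannel:
    knots_t: np.ndarray
    knots_r: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        xt, xr = self.knots_t, self.knots_r
        if xt.size == 1:
            return np.full_like(t, xr[0], dtype=float)
        out = np.interp(t, xt, xr)
        left = t < xt[0]
        right = t > xt[-1]
        if np.any(left):
            slope = (xr[1] - xr[0]) / (xt[1] - xt[0])
            out = np.where(left, xr[0] + slope * (t - xt[0]), out)
        if np.any(right):
            slope = (xr[-1] - xr[-2]) / (xt[-1] - xt[-2])
            out = np.where(right, xr[-1] + slope * (t - xt[-1]), out)
        return out


@dataclass
class DriftModel:
    """Windowed-mean, piecewise-linear residual-vs-time functions."""

    channels: dict[int, DriftChannel]
    window_h: float
    flagged: dict[int, bool] = field(default_factory=dict)

    def correction(self, mass: int, t):
        return self.channels[mass](t)


@dataclass
class ReductionConfig:
    """Options of the session correction pipeline."""

    mode: str = "carbonate"  # 'carbonate' or 'gas'
    drift_window_h: float = 48.0
    apply_drift: bool = True
    alpha: float = 0.05
    background: BackgroundModel | None = None
    wg_bulk: BulkComposition = field(default_factory=lambda: BulkComposition(-4.6, -5.0))
    constants: IsotopeConstants = BRAND_CONSTANTS
    gas_theory: GasTheory = field(default_factory=GasTheory)
    gas_d49_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("carbonate", "gas"):
            raise ValueError(f"mode must be 'carbonate' or 'gas', got {self.mode!r}")


@dataclass
class SessionResult:
    """Per-sample summary plus the fitted correction models."""

    samples: pd.DataFrame
    replicates: pd.DataFrame
    background: BackgroundModel | None
    nonlinearity: NonlinearityFit | None
    transfer: TransferFunction | None
    drift: DriftModel | None
    qc: "QCResult | None"
    config: ReductionConfig


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def summarize_replicates(values: Sequence[float]):
    """(mean, SD, 2 SE, n) of replicate Δ values.

    Sample SD uses the n−1 denominator; 2 SE = 2·SD/√n.  With a single
    replicate SD and SE are undefined (NaN).
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 1:
        raise ValueError("need at least one replicate")
    mean = float(arr.mean())
    if n == 1:
        return mean, float("nan"), float("nan"), 1
    sd = float(arr.std(ddof=1))
    return mean, sd, 2.0 * sd / math.sqrt(n), n


def background_correct(cycles: CycleIntensities, bg: BackgroundModel) -> CycleIntensities:
    """Apply m/z 47.5 background scaling to one cycle.

    ``i_corrected = i + s·i47_5`` for masses 47–49; masses 44–46 unchanged.
    With s = −1 and a negative monitored intensity this adds back the
    magnitude of the negative background.
    """
    if bg.is_zero:
        return cycles
    if cycles.i47_5 is None:
        raise ValueError("cycle carries no m/z 47.5 monitor intensity")
    b = cycles.i47_5
    return replace(
        cycles,
        i47=cycles.i47 + bg.s47 * b,
        i48=cycles.i48 + bg.s48 * b,
        i49=cycles.i49 + bg.s49 * b,
    )


def reduce_replicate(
    record: ReplicateRecord,
    background: BackgroundModel | None = None,
    wg_bulk: BulkComposition | None = None,
    const: IsotopeConstants = BRAND_CONSTANTS,
) -> RawClumpedValues:
    """Raw Δ/δ values of a replicate, applying the background correction
    first when cycle data are present."""
    if not record.has_cycles:
        if record.raw is None:
            raise ValueError(f"replicate {record.replicate_id!r} has no data")
        return record.raw
    bg = background or BackgroundModel()
    sample = [background_correct(c, bg) for c in record.sample_cycles]
    wg = [background_correct(c, bg) for c in record.wg_cycles]
    if wg_bulk is None:
        raise ValueError("working-gas bulk composition required to reduce cycles")
    return raw_deltas(sample, wg, wg_bulk, const)


# ---------------------------------------------------------------------------
# background scaling factors
# ---------------------------------------------------------------------------


def _prepare_cycle_arrays(records, wg_bulk, const):
    """Per-replicate cached arrays for the fast scaling-factor fit."""
    prepared = []
    for rec in records:
        s_cycles = rec.sample_cycles
        w_ref = bracket_working_gas(rec.wg_cycles)
        if any(c.i47_5 is None for c in s_cycles) or any(c.i47_5 is None for c in w_ref):
            raise ValueError(
                f"replicate {rec.replicate_id!r} lacks m/z 47.5 monitor intensities"
            )
        s = {
            "i44": np.array([c.i44 for c in s_cycles]),
            "i475": np.array([c.i47_5 for c in s_cycles]),
            47: np.array([c.i47 for c in s_cycles]),
            48: np.array([c.i48 for c in s_cycles]),
            49: np.array([c.i49 for c in s_cycles]),
        }
        w = {
            "i44": np.array([c.i44 for c in w_ref]),
            "i475": np.array([c.i47_5 for c in w_ref]),
            47: np.array([c.i47 for c in w_ref]),
            48: np.array([c.i48 for c in w_ref]),
            49: np.array([c.i49 for c in w_ref]),
        }
        # δ45/δ46 and hence the sample bulk are independent of the scaling
        # factor (masses 44–46 are never background-corrected).
        d45 = float(np.mean([
            ((c.i45 / c.i44) / (r.i45 / r.i44) - 1.0) * 1000.0
            for c, r in zip(s_cycles, w_ref)
        ]))
        d46 = float(np.mean([
            ((c.i46 / c.i44) / (r.i46 / r.i44) - 1.0) * 1000.0
            for c, r in zip(s_cycles, w_ref)
        ]))
        bulk = solve_bulk_composition(d45, d46, wg_bulk, const)
        prepared.append(
            {
                "s": s,
                "w": w,
                "st_sample": stochastic_ratios(bulk, const),
                "st_wg": stochastic_ratios(wg_bulk, const),
            }
        )
    return prepared


def _delta_vs_small_delta(prep, mass: int, s: float):
    """(δm, Δm_raw) per replicate for candidate scaling factor ``s``."""
    small, big = [], []
    for p in prep:
        sm, w = p["s"], p["w"]
        r_s = (sm[mass] + s * sm["i475"]) / sm["i44"]
        r_w = (w[mass] + s * w["i475"]) / w["i44"]
        dm = (r_s / r_w - 1.0) * 1000.0
        r_abs = p["st_wg"].by_mass(mass) * (1.0 + dm / 1000.0)
        bm = (r_abs / p["st_sample"].by_mass(mass) - 1.0) * 1000.0
        small.append(float(dm.mean()))
        big.append(float(bm.mean()))
    return np.asarray(small), np.asarray(big)


def fit_scaling_factors(
    records: Iterable[ReplicateRecord],
    accepted: AcceptedStandards = DEFAULT_STANDARDS,
    wg_bulk: BulkComposition | None = None,
    const: IsotopeConstants = BRAND_CONSTANTS,
    bracket: tuple[float, float] = (-2.0, 0.5),
    session_id: str = "",
) -> BackgroundModel:
    """Determine m/z 47.5 scaling factors from the ETH 1 + ETH 2 replicates.

    Per channel, the factor is the root (bisection-type bracketed search) of
    the OLS slope of Δ(raw) vs δ across the two standards, which share
    identical accepted Δ values but span a wide δ range.
    """
    if wg_bulk is None:
        raise ValueError("working-gas bulk composition required")
    recs = [
        r
        for r in records
        if r.has_cycles and _norm_name(r.sample_id) in ("ETH-1", "ETH-2")
    ]
    if len({_norm_name(r.sample_id) for r in recs}) < 2:
        raise MissingStandardsError(
            "scaling-factor fit needs cycle data for both ETH 1 and ETH 2"
        )
    prep = _prepare_cycle_arrays(recs, wg_bulk, const)

    max_bg = max(
        float(np.max(np.abs(p["s"]["i475"]))) for p in prep
    )
    if max_bg < 1e-9:
        return BackgroundModel(
            session_id=session_id,
            degenerate={47: True, 48: True, 49: True},
            residual_slopes={47: 0.0, 48: 0.0, 49: 0.0},
        )

    factors: dict[int, float] = {}
    degenerate: dict[int, bool] = {}
    residual: dict[int, float] = {}
    for mass in (47, 48, 49):

        def slope_of(s: float) -> float:
            x, y = _delta_vs_small_delta(prep, mass, s)
            return float(np.polyfit(x, y, 1)[0])

        lo, hi = bracket
        f_lo, f_hi = slope_of(lo), slope_of(hi)
        if f_lo * f_hi > 0.0:
            if max(abs(f_lo), abs(f_hi)) < 1e-8:
                factors[mass], degenerate[mass] = 0.0, True
                residual[mass] = 0.0
                continue
            raise FitError(
                f"no scaling-factor root for Δ{mass} in [{lo}, {hi}] "
                f"(slopes {f_lo:.3e} / {f_hi:.3e})"
            )
        root = float(brentq(slope_of, lo, hi, xtol=1e-7))
        factors[mass], degenerate[mass] = root, False
        residual[mass] = slope_of(root)

    return BackgroundModel(
        s47=factors[47],
        s48=factors[48],
        s49=factors[49],
        session_id=session_id,
        degenerate=degenerate,
        residual_slopes=residual,
    )


# ---------------------------------------------------------------------------
# gas non-linearity
# ---------------------------------------------------------------------------


def _raw_frame(records, background, wg_bulk, const) -> pd.DataFrame:
    rows = []
    for rec in records:
        raw = reduce_replicate(rec, background, wg_bulk, const) if rec.has_cycles else rec.raw
        rows.append(
            {
                "replicate_id": rec.replicate_id,
                "sample_id": rec.sample_id,
                "role": rec.role,
                "session_id": rec.session_id,
                "timestamp_h": rec.timestamp_h,
                "d45": raw.d45,
                "d46": raw.d46,
                "d47": raw.d47,
                "d48": raw.d48,
                "d49": raw.d49,
                "D47_raw": raw.D47_raw,
                "D48_raw": raw.D48_raw,
                "D49_raw": raw.D49_raw,
                "d13C": raw.d13c,
                "d18O": raw.d18o,
            }
        )
    return pd.DataFrame(rows)


def fit_gas_nonlinearity(
    gas_records: Iterable[ReplicateRecord],
    alpha: float = 0.05,
    wg_bulk: BulkComposition | None = None,
    const: IsotopeConstants = BRAND_CONSTANTS,
    incompatible_z: float = 4.0,
) -> NonlinearityFit:
    """Δ(raw)-vs-δ slopes from the equilibrated-gas families.

    Per channel the two families (25 °C, 1000 °C) are fitted separately and
    their slopes compared (two-sided z test on the slope difference): a
    discrepancy significant at ``alpha`` is warned about, while a clearly
    incompatible pair (|z| ≥ ``incompatible_z``) is an error, since merging
    the families would then be meaningless.  The merged-data slope is
    returned; a channel needs correction when its merged slope is
    resolvable (|slope| > 2 SE).
    """
    recs = [r for r in gas_records if r.role in GAS_ROLES]
    if not recs:
        raise MissingStandardsError("no equilibrated-gas replicates supplied")
    df = _raw_frame(recs, None, wg_bulk, const)
    families = {role: df[df["role"] == role] for role in GAS_ROLES}
    present = [role for role, sub in families.items() if len(sub) >= 3]
    if not present:
        raise MissingStandardsError("need ≥ 3 replicates of at least one gas family")
    if len(present) == 1:
        warnings.warn(
            f"only one gas family present ({present[0]}); "
            "merged slope equals that family's slope",
            stacklevel=2,
        )

    slopes: dict[int, tuple[float, float]] = {}
    needs: dict[int, bool] = {}
    fam_fits: dict[str, dict[int, tuple[float, float]]] = {r: {} for r in present}
    fam_icpt: dict[str, dict[int, float]] = {r: {} for r in present}
    for mass in (47, 48, 49):
        xcol, ycol = f"d{mass}", f"D{mass}_raw"
        per_family = {}
        for role in present:
            sub = families[role]
            res = stats.linregress(sub[xcol], sub[ycol])
            per_family[role] = res
            fam_fits[role][mass] = (float(res.slope), float(res.stderr))
            fam_icpt[role][mass] = float(res.intercept)
        if len(present) == 2:
            r1, r2 = (per_family[role] for role in present)
            denom = math.hypot(r1.stderr, r2.stderr)
            z = (r1.slope - r2.slope) / denom if denom > 0 else 0.0
            p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
            msg = (
                f"Δ{mass}: gas families differ in non-linearity slope "
                f"({r1.slope:.5f} vs {r2.slope:.5f}, z = {z:.2f}, p = {p:.3g})"
            )
            if abs(z) >= incompatible_z:
                raise FitError(msg)
            if p < alpha:
                warnings.warn(msg, stacklevel=2)
        # merged slope: common slope with per-family intercepts (the two
        # families sit at different equilibrium Δ, so naive pooling would
        # alias the intercept contrast into the slope)
        sxx = syx = rss_n = 0.0
        n_tot = 0
        for role in present:
            sub = families[role]
            xc = sub[xcol] - sub[xcol].mean()
            yc = sub[ycol] - sub[ycol].mean()
            sxx += float((xc * xc).sum())
            syx += float((xc * yc).sum())
            n_tot += len(sub)
        slope = syx / sxx
        for role in present:
            sub = families[role]
            resid = (sub[ycol] - sub[ycol].mean()) - slope * (sub[xcol] - sub[xcol].mean())
            rss_n += float((resid * resid).sum())
        dof = max(n_tot - 2 * len(present), 1)
        se = math.sqrt(rss_n / dof / sxx) if sxx > 0 else float("inf")
        slopes[mass] = (float(slope), float(se))
        needs[mass] = abs(slope) > 2.0 * se
        for role in present:
            sub = families[role]
            # representative family value, consistent with how the data are
            # corrected: δ=0 intercept when the slope is applied, plain mean
            # otherwise
            if needs[mass]:
                fam_icpt[role][mass] = float(sub[ycol].mean() - slope * sub[xcol].mean())
            else:
                fam_icpt[role][mass] = float(sub[ycol].mean())

    return NonlinearityFit(
        slopes=slopes,
        needs_correction=needs,
        family_fits=fam_fits,
        family_intercepts=fam_icpt,
    )


# ---------------------------------------------------------------------------
# transfer function and drift
# ---------------------------------------------------------------------------


def fit_transfer_function(
    measured_means: dict[str, tuple[float, float]],
    accepted: AcceptedStandards = DEFAULT_STANDARDS,
) -> TransferFunction:
    """Empirical transfer function: accepted = slope·measured + intercept.

    ``measured_means`` maps standard name to its session-mean
    non-linearity-corrected (Δ47_raw, Δ48_raw).
    """
    if len(measured_means) < 2:
        raise MissingStandardsError(
            "transfer-function fit needs ≥ 2 standards with accepted values"
        )
    channels = {}
    for idx, mass in ((0, 47), (1, 48)):
        xs, ys = [], []
        for name, pair in measured_means.items():
            xs.append(pair[idx])
            ys.append(accepted.accepted(name)[idx])
        if len(set(np.round(ys, 12))) < 2:
            raise FitError(
                f"transfer-function fit for Δ{mass} is rank deficient: "
                "all accepted values identical"
            )
        a, b = np.polyfit(xs, ys, 1)
        channels[mass] = (float(a), float(b))
    return TransferFunction(channels=channels)


def fit_drift(
    standard_residuals: dict[int, Sequence[tuple[float, float]]],
    window_h: float = 48.0,
) -> DriftModel:
    """Windowed-mean piecewise-linear residual-vs-time model per channel.

    ``standard_residuals`` maps channel (47/48) to (timestamp_h, residual)
    pairs of the standards.  Knots are the per-window mean time/residual;
    evaluation interpolates linearly with linear end extrapolation.
    """
    channels: dict[int, DriftChannel] = {}
    flagged: dict[int, bool] = {}
    for mass, pairs in standard_residuals.items():
        arr = np.asarray(pairs, dtype=float)
        if arr.shape[0] < 5:
            raise FitError(
                f"drift fit for Δ{mass} needs ≥ 5 standard replicates, got {arr.shape[0]}"
            )
        t, r = arr[:, 0], arr[:, 1]
        span = float(t.max() - t.min())
        if window_h >= span or span == 0.0:
            warnings.warn(
                f"drift window ({window_h:g} h) is not smaller than the session span "
                f"({span:g} h); using a constant (mean) drift model",
                stacklevel=2,
            )
            channels[mass] = DriftChannel(
                knots_t=np.array([float(t.mean())]), knots_r=np.array([float(r.mean())])
            )
        else:
            edges = np.arange(t.min(), t.max() + window_h, window_h)
            kt, kr = [], []
            for lo, hi in zip(edges[:-1], edges[1:]):
                mask = (t >= lo) & (t < hi) if hi < edges[-1] else (t >= lo) & (t <= hi)
                if mask.any():
                    kt.append(float(t[mask].mean()))
                    kr.append(float(r[mask].mean()))
            channels[mass] = DriftChannel(knots_t=np.asarray(kt), knots_r=np.asarray(kr))
        limit = DRIFT_FLAG_LIMITS.get(mass)
        flagged[mass] = bool(
            limit is not None and np.max(np.abs(channels[mass](t))) > limit
        )
        if flagged[mass]:
            warnings.warn(
                f"drift correction for Δ{mass} exceeds {limit}‰; "
                "inspect the session before trusting the correction",
                stacklevel=2,
            )
    return DriftModel(channels=channels, window_h=window_h, flagged=flagged)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class QCResult:
    """Advisory quality-control flags for a session."""

    replicate_d49_flag: pd.Series  # indexed like the replicate frame
    gas_d49_range: tuple[float, float] | None
    sample_corr: dict[str, tuple[float, float, bool]]  # r, p, flagged
    standard_normality: dict[str, dict[int, tuple[float, float]]]  # W, p


def qc_checks(
    replicates: pd.DataFrame,
    gas_d49_range: tuple[float, float] | None = None,
    alpha: float = 0.05,
    accepted: AcceptedStandards = DEFAULT_STANDARDS,
) -> QCResult:
    """Contamination and distribution checks on a reduced replicate frame.

    * per replicate: Δ49(raw) outside the equilibrated-gas range flags
      possible contamination;
    * per sample: a significant Δ48(raw)–Δ49(raw) Pearson correlation flags
      contamination leaking into Δ48;
    * per standard: Shapiro–Wilk W of the final Δ47/Δ48 populations.
    All flags are advisory.
    """
    gas_mask = replicates["role"].isin(GAS_ROLES)
    if gas_d49_range is None and gas_mask.any():
        gas_d49 = replicates.loc[gas_mask, "D49_raw"]
        gas_d49_range = (float(gas_d49.min()), float(gas_d49.max()))

    if gas_d49_range is not None:
        lo, hi = gas_d49_range
        d49_flag = ~replicates["D49_raw"].between(lo, hi)
        d49_flag[gas_mask] = False
    else:
        d49_flag = pd.Series(False, index=replicates.index)

    sample_corr: dict[str, tuple[float, float, bool]] = {}
    for sample_id, sub in replicates[~gas_mask].groupby("sample_id"):
        if len(sub) < 3 or sub["D48_raw"].std() < 1e-9 or sub["D49_raw"].std() < 1e-9:
            continue
        r, p = stats.pearsonr(sub["D48_raw"], sub["D49_raw"])
        sample_corr[sample_id] = (float(r), float(p), bool(p < alpha))

    normality: dict[str, dict[int, tuple[float, float]]] = {}
    for sample_id, sub in replicates[~gas_mask].groupby("sample_id"):
        if _norm_name(sample_id) not in accepted or len(sub) < 3:
            continue
        normality[sample_id] = {}
        for mass in (47, 48):
            col = f"D{mass}_final" if f"D{mass}_final" in sub else f"D{mass}_raw"
            w, p = stats.shapiro(sub[col])
            normality[sample_id][mass] = (float(w), float(p))

    return QCResult(
        replicate_d49_flag=d49_flag,
        gas_d49_range=gas_d49_range,
        sample_corr=sample_corr,
        standard_normality=normality,
    )


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def apply_pipeline(
    records: Sequence[ReplicateRecord],
    accepted: AcceptedStandards = DEFAULT_STANDARDS,
    config: ReductionConfig | None = None,
) -> SessionResult:
    """Run the full correction chain on a session of replicates.

    Non-linearity → transfer function → drift, in that fixed order, then
    per-sample aggregation and QC.  Standards are carried through their own
    correction (their summaries reproduce the accepted values in the
    least-squares sense).
    """
    cfg = config or ReductionConfig()
    records = list(records)
    if not records:
        raise ReductionError("empty session")
    carb = [r for r in records if r.role not in GAS_ROLES]
    gases = [r for r in records if r.role in GAS_ROLES]
    anchor_names = {
        _norm_name(r.sample_id) for r in carb if r.role == "anchor_standard"
    } & set(accepted.names())
    if len(anchor_names) < 2:
        raise MissingStandardsError(
            "session needs ≥ 2 anchor standards with accepted values; found "
            f"{sorted(anchor_names)}"
        )

    # 1) non-linearity -------------------------------------------------------
    background = cfg.background
    nlfit: NonlinearityFit | None = None
    if cfg.mode == "carbonate":
        if background is None and any(r.has_cycles for r in carb):
            background = fit_scaling_factors(
                carb, accepted, cfg.wg_bulk, cfg.constants,
                session_id=records[0].session_id,
            )
        df = _raw_frame(records, background, cfg.wg_bulk, cfg.constants)
        for mass in (47, 48, 49):
            df[f"D{mass}_nl"] = df[f"D{mass}_raw"]
    else:
        df = _raw_frame(records, background, cfg.wg_bulk, cfg.constants)
        if not gases:
            raise MissingStandardsError("gas mode requires equilibrated-gas replicates")
        nlfit = fit_gas_nonlinearity(
            gases, alpha=cfg.alpha, wg_bulk=cfg.wg_bulk, const=cfg.constants
        )
        for mass in (47, 48, 49):
            slope, _ = nlfit.slopes[mass]
            if nlfit.needs_correction[mass]:
                df[f"D{mass}_nl"] = df[f"D{mass}_raw"] - slope * df[f"d{mass}"]
            else:
                df[f"D{mass}_nl"] = df[f"D{mass}_raw"]

    carb_mask = ~df["role"].isin(GAS_ROLES)

    # 2) transfer to CDES90 --------------------------------------------------
    if cfg.mode == "carbonate":
        anchors = df[carb_mask & (df["role"] == "anchor_standard")]
        measured = {
            name: (float(sub["D47_nl"].mean()), float(sub["D48_nl"].mean()))
            for name, sub in anchors.groupby("sample_id")
            if _norm_name(name) in accepted
        }
        transfer = fit_transfer_function(measured, accepted)
    else:
        assert nlfit is not None
        roles = [r for r in GAS_ROLES if r in nlfit.family_intercepts]
        if len(roles) < 2:
            raise MissingStandardsError(
                "gas-mode transfer function needs both gas families"
            )
        channels = {}
        for idx, mass in ((0, 47), (1, 48)):
            xs = [nlfit.family_intercepts[role][mass] for role in roles]
            # the family intercept is its Δ at δ = 0 after the slope
            # correction, so apply the same convention used on the data
            if nlfit.needs_correction[mass]:
                pass  # intercepts are already the δ=0 values
            ys = [cfg.gas_theory.pair(role)[idx] for role in roles]
            a, b = np.polyfit(xs, ys, 1)
            channels[mass] = (float(a), float(b))
        transfer = TransferFunction(channels=channels)
    for mass in (47, 48):
        df[f"D{mass}_uc"] = transfer.apply(mass, df[f"D{mass}_nl"])

    # 3) drift ---------------------------------------------------------------
    drift: DriftModel | None = None
    std_mask = carb_mask & df["role"].isin(["anchor_standard", "check_standard"])
    std_mask &= df["sample_id"].map(lambda s: _norm_name(s) in accepted)
    if cfg.apply_drift:
        n_std = int(std_mask.sum())
        if n_std >= 5:
            residuals = {}
            for mass in (47, 48):
                idx = 0 if mass == 47 else 1
                res = [
                    (row["timestamp_h"],
                     row[f"D{mass}_uc"] - accepted.accepted(row["sample_id"])[idx])
                    for _, row in df[std_mask].iterrows()
                ]
                residuals[mass] = res
            drift = fit_drift(residuals, window_h=cfg.drift_window_h)
            for mass in (47, 48):
                df[f"D{mass}_final"] = df[f"D{mass}_uc"] - drift.correction(
                    mass, df["timestamp_h"].to_numpy()
                )
        else:
            warnings.warn(
                f"only {n_std} standard replicates; drift correction skipped",
                stacklevel=2,
            )
    if drift is None:
        for mass in (47, 48):
            df[f"D{mass}_final"] = df[f"D{mass}_uc"]

    # 4) QC ------------------------------------------------------------------
    qc = qc_checks(df, gas_d49_range=cfg.gas_d49_range, alpha=cfg.alpha,
                   accepted=accepted)

    # 5) per-sample aggregation ---------------------------------------------
    rows = []
    for sample_id, sub in df[carb_mask].groupby("sample_id", sort=False):
        keep = ~qc.replicate_d49_flag.reindex(sub.index, fill_value=False)
        n_flagged = int((~keep).sum())
        if not keep.any():
            raise ReductionError(
                f"all {len(sub)} replicates of sample {sample_id!r} failed the Δ49 QC"
            )
        good = sub[keep]
        m47, sd47, se47, n = summarize_replicates(good["D47_final"])
        m48, sd48, se48, _ = summarize_replicates(good["D48_final"])
        corr = qc.sample_corr.get(sample_id)
        rows.append(
            {
                "sample_id": sample_id,
                "role": sub["role"].iloc[0],
                "n": n,
                "d47": m47, "sd47": sd47, "se47_2": se47,
                "d48": m48, "sd48": sd48, "se48_2": se48,
                "d13C": float(good["d13C"].mean()),
                "d18O": float(good["d18O"].mean()),
                "n_d49_flagged": n_flagged,
                "d48_d49_corr_flag": bool(corr[2]) if corr else False,
            }
        )
    samples = pd.DataFrame(rows)

    return SessionResult(
        samples=samples,
        replicates=df,
        background=background,
        nonlinearity=nlfit,
        transfer=transfer,
        drift=drift,
        qc=qc,
        config=cfg,
    )
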