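"""Bulk-composition and CO2-isotopologue arithmetic.

Stochastic reference ratios and raw δ45–δ49 / Δ47–Δ49 values are computed
under a single editable set of isotopic parameters (the IUPAC/Brand
assessment): ¹³C/¹²C of VPDB, ¹⁸O/¹⁶O and ¹⁷O/¹⁶O of VSMOW, and the
triple-oxygen exponent λ relating R17 to R18.

Conventions
-----------
* Bulk compositions are (δ13C vs VPDB, δ18O vs VPDB-CO2).  The VPDB-CO2 gas
  scale relates to VSMOW through a constant ratio factor; the 90 °C
  acid-digestion ¹⁸O fractionation is a reporting constant only and never
  enters Δ arithmetic.
* The working gas is treated as stochastic at its known bulk composition
  when converting measured δ values into absolute isotopologue ratios; any
  departure of the working gas from the stochastic distribution is absorbed
  by the session-level standardisation (transfer function).
* Each sample cycle is compared against the mean of the two bracketing
  working-gas cycles (the final sample cycle against the final working-gas
  cycle), a documented convention.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "IsotopeConstants",
    "BRAND_CONSTANTS",
    "BulkComposition",
    "CycleIntensities",
    "RawClumpedValues",
    "StochasticRatios",
    "DEFAULT_GAINS",
    "isotope_ratios",
    "stochastic_ratios",
    "solve_bulk_composition",
    "intensities_from_composition",
    "raw_deltas",
]

#: Per-mass amplifier gains (masses 45–49) relative to the m/z 44 channel,
#: mimicking the resistor ladder of a multicollector instrument.  Gains are
#: identical for sample and working gas and therefore cancel in every δ and
#: Δ; they only set the size of the rare-isotopologue beams relative to an
#: additive background.
DEFAULT_GAINS = (1.0, 1.0, 1.0e3, 1.0e4, 1.0e5)


@dataclass(frozen=True)
class IsotopeConstants:
    """Isotopic parameters for CO2 isotopologue arithmetic."""

    r13_vpdb: float = 0.011180
    r18_vsmow: float = 0.0020052
    r17_vsmow: float = 0.00038475
    lambda_17: float = 0.528
    #: R18(VPDB-CO2 reference) / R18(VSMOW): ties the δ18O gas scale used
    #: for bulk compositions to the VSMOW ratio scale.
    r18_vpdb_co2_factor: float = 1.04143
    #: 90 °C phosphoric-acid ¹⁸O fractionation (reporting of carbonate
    #: δ18O only; never used for Δ values).
    acid_18o_alpha_90c: float = 1.00813

    def __post_init__(self) -> None:
        for name in ("r13_vpdb", "r18_vsmow", "r17_vsmow", "r18_vpdb_co2_factor",
                     "acid_18o_alpha_90c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.5 < self.lambda_17 < 0.53):
            raise ValueError(f"lambda_17 must lie in (0.5, 0.53), got {self.lambda_17}")

    @property
    def r18_vpdb_co2(self) -> float:
        return self.r18_vsmow * self.r18_vpdb_co2_factor


BRAND_CONSTANTS = IsotopeConstants()


@dataclass(frozen=True)
class BulkComposition:
    """Bulk composition of a CO2 gas: δ13C vs VPDB, δ18O vs VPDB-CO2 (‰)."""

    d13c: float
    d18o: float

    def __post_init__(self) -> None:
        if self.d13c <= -1000.0 or self.d18o <= -1000.0:
            raise ValueError("δ values must exceed −1000‰")
        if not (math.isfinite(self.d13c) and math.isfinite(self.d18o)):
            raise ValueError("δ values must be finite")


@dataclass(frozen=True)
class StochasticRatios:
    """Isotopologue/mass-44 abundance ratios of a stochastic population."""

    r45: float
    r46: float
    r47: float
    r48: float
    r49: float

    def by_mass(self, mass: int) -> float:
        return {45: self.r45, 46: self.r46, 47: self.r47, 48: self.r48, 49: self.r49}[mass]


@dataclass(frozen=True)
class CycleIntensities:
    """Ion-beam intensities (mV) of one integration cycle."""

    i44: float
    i45: float
    i46: float
    i47: float
    i48: float
    i49: float
    i47_5: float | None = None
    side: str = "sample"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.i44) and self.i44 > 0):
            raise ValueError(f"i44 must be positive and finite, got {self.i44!r}")

    def by_mass(self, mass: int) -> float:
        return {44: self.i44, 45: self.i45, 46: self.i46,
                47: self.i47, 48: self.i48, 49: self.i49}[mass]


@dataclass(frozen=True)
class RawClumpedValues:
    """Working-gas-relative δ values and stochastic-reference Δ values (‰)."""

    d45: float
    d46: float
    d47: float
    d48: float
    d49: float
    D47_raw: float
    D48_raw: float
    D49_raw: float
    d13c: float
    d18o: float


def isotope_ratios(bulk: BulkComposition, const: IsotopeConstants = BRAND_CONSTANTS):
    """(R13, R17, R18) of a gas from its bulk composition.

    R17 follows the triple-oxygen power law
    R17 = r17_vsmow · (R18/r18_vsmow)^λ.
    """
    r13 = const.r13_vpdb * (1.0 + bulk.d13c / 1000.0)
    r18 = const.r18_vpdb_co2 * (1.0 + bulk.d18o / 1000.0)
    r17 = const.r17_vsmow * (r18 / const.r18_vsmow) ** const.lambda_17
    return r13, r17, r18


def stochastic_ratios(
    bulk: BulkComposition, const: IsotopeConstants = BRAND_CONSTANTS
) -> StochasticRatios:
    """Stochastic isotopologue abundance ratios (relative to mass 44).

    Multinomial combination of the carbon (¹²C/¹³C) and two oxygen
    (¹⁶O/¹⁷O/¹⁸O) positions of CO2.
    """
    r13, r17, r18 = isotope_ratios(bulk, const)
    return StochasticRatios(
        r45=r13 + 2.0 * r17,
        r46=2.0 * r18 + 2.0 * r13 * r17 + r17 * r17,
        r47=2.0 * r13 * r18 + 2.0 * r17 * r18 + r13 * r17 * r17,
        r48=r18 * r18 + 2.0 * r13 * r17 * r18,
        r49=r13 * r18 * r18,
    )


def solve_bulk_composition(
    d45: float,
    d46: float,
    wg_bulk: BulkComposition,
    const: IsotopeConstants = BRAND_CONSTANTS,
) -> BulkComposition:
    """Bulk composition of a sample gas from its δ45 and δ46 vs working gas.

    Inverts the stochastic R45/R46 expressions with the λ power-law
    constraint on R17 via a bracketed root search in R18.
    """
    wg = stochastic_ratios(wg_bulk, const)
    r45_s = wg.r45 * (1.0 + d45 / 1000.0)
    r46_s = wg.r46 * (1.0 + d46 / 1000.0)
    k = const.r17_vsmow / const.r18_vsmow**const.lambda_17

    def f(r18: float) -> float:
        r17 = k * r18**const.lambda_17
        r13 = r45_s - 2.0 * r17
        return 2.0 * r18 + 2.0 * r13 * r17 + r17 * r17 - r46_s

    r18 = brentq(f, 1.0e-4, 1.0e-2, xtol=1e-18, rtol=8.9e-16)
    r17 = k * r18**const.lambda_17
    r13 = r45_s - 2.0 * r17
    return BulkComposition(
        d13c=(r13 / const.r13_vpdb - 1.0) * 1000.0,
        d18o=(r18 / const.r18_vpdb_co2 - 1.0) * 1000.0,
    )


def intensities_from_composition(
    bulk: BulkComposition,
    D47: float = 0.0,
    D48: float = 0.0,
    D49: float = 0.0,
    i44: float = 16000.0,
    gains: Sequence[float] = DEFAULT_GAINS,
    i47_5: float = 0.0,
    side: str = "sample",
    const: IsotopeConstants = BRAND_CONSTANTS,
) -> CycleIntensities:
    """Forward model: beam intensities of a gas of known composition.

    Masses 45 and 46 carry the stochastic abundances (Δ45 = Δ46 = 0);
    masses 47–49 are scaled by their clumped excesses.
    """
    st = stochastic_ratios(bulk, const)
    g45, g46, g47, g48, g49 = gains
    return CycleIntensities(
        i44=i44,
        i45=st.r45 * i44 * g45,
        i46=st.r46 * i44 * g46,
        i47=st.r47 * (1.0 + D47 / 1000.0) * i44 * g47,
        i48=st.r48 * (1.0 + D48 / 1000.0) * i44 * g48,
        i49=st.r49 * (1.0 + D49 / 1000.0) * i44 * g49,
        i47_5=i47_5,
        side=side,
    )


def bracket_working_gas(wg_cycles: Sequence[CycleIntensities]) -> list[CycleIntensities]:
    """Working-gas reference for each sample cycle: the mean of the adjacent
    working-gas cycles; the last sample cycle is referenced to the last
    working-gas cycle alone."""
    n = len(wg_cycles)
    out = []
    for k in range(n):
        a = wg_cycles[k]
        b = wg_cycles[min(k + 1, n - 1)]
        out.append(
            CycleIntensities(
                i44=0.5 * (a.i44 + b.i44),
                i45=0.5 * (a.i45 + b.i45),
                i46=0.5 * (a.i46 + b.i46),
                i47=0.5 * (a.i47 + b.i47),
                i48=0.5 * (a.i48 + b.i48),
                i49=0.5 * (a.i49 + b.i49),
                i47_5=(
                    None
                    if a.i47_5 is None or b.i47_5 is None
                    else 0.5 * (a.i47_5 + b.i47_5)
                ),
                side="working_gas",
            )
        )
    return out


def raw_deltas(
    sample_cycles: Sequence[CycleIntensities],
    wg_cycles: Sequence[CycleIntensities],
    wg_bulk: BulkComposition,
    const: IsotopeConstants = BRAND_CONSTANTS,
) -> RawClumpedValues:
    """Reduce matched sample/working-gas cycles to raw δ and Δ values.

    Per cycle, δm is the sample/working-gas intensity-ratio contrast for
    mass m.  The sample bulk composition is solved from the mean δ45/δ46;
    Δm(raw) = (Rm/Rm* − 1)·1000 against the sample's own stochastic
    distribution, averaged over cycles.
    """
    if len(sample_cycles) != len(wg_cycles):
        raise ValueError(
            f"cycle-count mismatch: {len(sample_cycles)} sample vs "
            f"{len(wg_cycles)} working-gas cycles"
        )
    if not sample_cycles:
        raise ValueError("no cycles supplied")
    wg_ref = bracket_working_gas(wg_cycles)

    masses = (45, 46, 47, 48, 49)
    deltas = np.empty((len(sample_cycles), 5))
    for i, (s, w) in enumerate(zip(sample_cycles, wg_ref)):
        for j, m in enumerate(masses):
            deltas[i, j] = ((s.by_mass(m) / s.i44) / (w.by_mass(m) / w.i44) - 1.0) * 1000.0

    d_mean = deltas.mean(axis=0)
    bulk = solve_bulk_composition(d_mean[0], d_mean[1], wg_bulk, const)
    st_sample = stochastic_ratios(bulk, const)
    st_wg = stochastic_ratios(wg_bulk, const)

    # Absolute sample ratios per cycle via the working gas (stochastic at
    # its bulk composition), then excess over the sample's own stochastic
    # distribution.
    big_deltas = {}
    for j, m in zip((2, 3, 4), (47, 48, 49)):
        r_sample = st_wg.by_mass(m) * (1.0 + deltas[:, j] / 1000.0)
        big_deltas[m] = float(np.mean((r_sample / st_sample.by_mass(m) - 1.0) * 1000.0))

    return RawClumpedValues(
        d45=float(d_mean[0]),
        d46=float(d_mean[1]),
        d47=float(d_mean[2]),
        d48=float(d_mean[3]),
        d49=float(d_mean[4]),
        D47_raw=big_deltas[47],
        D48_raw=big_deltas[48],
        D49_raw=big_deltas[49],
        d13c=bulk.d13c,
        d18o=bulk.d18o,
    )
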