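"""Crop physiology and yield metrics.

Measurement formulas used in rice drought-physiology work:

- relative water content          RWC% = (FW - DW) / (RW - DW) x 100
- instantaneous water-use eff.    WUEi = Pn / E
- gravimetric water-use eff.      WUEg = (BIO45 - BIO31) / WUc,  WUc = sum(daily WU)
- PSII maximum quantum yield      Fv/Fm = (Fm - Fo) / Fm
- qPCR relative expression        2^-ddCt against a reference gene and calibrator
- ChIP fold enrichment            dCt = Ct(target) - Ct(nonspecific Ab), 2^-ddCt
- yield components                spikelet fertility, single-grain weight,
                                  harvest index, % grain-yield increase vs WT

Units are carried as documentation only; inputs are assumed pre-converted
(weights in g, gas exchange in umol/mmol m^-2 s^-1, Ct in cycles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import DataError


@dataclass
class WaterStatusRecord:
    """Fresh (FW), rehydrated (RW) and dry (DW) leaf weights in g."""

    FW: float
    RW: float
    DW: float

    def __post_init__(self) -> None:
        if not (self.RW >= self.FW >= self.DW > 0):
            raise DataError("water status requires RW >= FW >= DW > 0")


@dataclass
class GasExchangeRecord:
    """Net assimilation Pn (umol CO2 m^-2 s^-1), transpiration E (mmol H2O m^-2 s^-1)."""

    Pn: float
    E: float


@dataclass
class GravimetricRecord:
    """Shoot dry biomass at 31/45 days after planting (g) and daily water additions (g)."""

    BIO31: float
    BIO45: float
    daily_WU: Sequence[float]

    def __post_init__(self) -> None:
        if self.BIO31 < 0 or self.BIO45 < 0:
            raise DataError("biomass must be non-negative")

    @property
    def WUc(self) -> float:
        """Cumulative water use: sum of the daily additions."""
        return float(sum(self.daily_WU))


@dataclass
class FluorescenceRecord:
    """Dark-adapted minimum (Fo) and maximum (Fm) chlorophyll fluorescence."""

    Fo: float
    Fm: float

    def __post_init__(self) -> None:
        if self.Fo < 0:
            raise DataError("Fo must be >= 0")


@dataclass
class CtRecord:
    """qPCR threshold cycles for one sample.

    For relative expression, ``target``/``reference`` hold the Ct values of
    the gene of interest and the reference gene.  For ChIP, ``target`` is the
    specific-antibody Ct and ``reference`` the nonspecific-antibody Ct.
    """

    target: float
    reference: float

    def __post_init__(self) -> None:
        for v in (self.target, self.reference):
            if not math.isfinite(v) or v <= 0:
                raise DataError("Ct values must be finite and positive")

    @property
    def dCt(self) -> float:
        return self.target - self.reference


@dataclass
class YieldComponents:
    """Yield component measurements for one plant/genotype mean."""

    NP: float = math.nan            # panicles per plant
    PL: float = math.nan            # panicle length (cm)
    NSP: float = math.nan           # spikelets per panicle
    NFG: float = math.nan           # filled grains per plant
    NGP: float = math.nan           # grains per panicle
    GY: float = math.nan            # grain weight per plant (g)
    total_spikelets: float = math.nan
    filled_spikelets: float = math.nan
    above_ground_DW: float = math.nan  # g
    grain_number: float = math.nan

    def __post_init__(self) -> None:
        if (
            math.isfinite(self.filled_spikelets)
            and math.isfinite(self.total_spikelets)
            and self.filled_spikelets > self.total_spikelets
        ):
            raise DataError("filled spikelets cannot exceed total spikelets")
        if math.isfinite(self.GY) and self.GY < 0:
            raise DataError("grain yield must be >= 0")


def relative_water_content(rec: WaterStatusRecord) -> float:
    """RWC% = (FW - DW) / (RW - DW) x 100."""
    if rec.RW <= rec.DW:
        raise DataError("RWC undefined: RW must exceed DW")
    return 100.0 * (rec.FW - rec.DW) / (rec.RW - rec.DW)


def wue_instantaneous(rec: GasExchangeRecord) -> float:
    """WUEi = Pn / E."""
    if rec.E <= 0:
        raise DataError("WUEi undefined: transpiration E must be positive")
    return rec.Pn / rec.E


def wue_gravimetric(rec: GravimetricRecord) -> float:
    """WUEg = (BIO45 - BIO31) / cumulative water use."""
    wuc = rec.WUc
    if wuc <= 0:
        raise DataError("WUEg undefined: cumulative water use must be positive")
    return (rec.BIO45 - rec.BIO31) / wuc


def fv_over_fm(rec: FluorescenceRecord) -> float:
    """Fv/Fm = (Fm - Fo) / Fm, the maximum photochemical efficiency of PSII."""
    if rec.Fm <= rec.Fo:
        raise DataError("Fv/Fm undefined: Fm must exceed Fo")
    return (rec.Fm - rec.Fo) / rec.Fm


def ddct_relative_expression(treatment: CtRecord, calibrator: CtRecord) -> float:
    """Relative expression 2^-ddCt of treatment vs calibrator sample."""
    ddct = treatment.dCt - calibrator.dCt
    return 2.0 ** (-ddct)


def chip_fold_enrichment(sample: CtRecord, calibrator: CtRecord) -> float:
    """ChIP-qPCR fold enrichment: dCt per record, then 2^-(dCt_s - dCt_cal)."""
    return 2.0 ** (-(sample.dCt - calibrator.dCt))


@dataclass
class YieldSummary:
    """Derived yield components; a field is NaN when its denominator is zero,
    with the reason recorded in ``errors``."""

    spikelet_fertility: float
    single_grain_weight: float
    harvest_index: float
    errors: dict[str, str] = field(default_factory=dict)


def yield_summary(rec: YieldComponents) -> YieldSummary:
    """Spikelet fertility, average single-grain weight and harvest index."""
    errors: dict[str, str] = {}
    if rec.total_spikelets > 0:
        fertility = rec.filled_spikelets / rec.total_spikelets
    else:
        fertility = math.nan
        errors["spikelet_fertility"] = "total spikelets must be positive"
    if rec.grain_number > 0:
        sgw = rec.GY / rec.grain_number
    else:
        sgw = math.nan
        errors["single_grain_weight"] = "grain number must be positive"
    if rec.above_ground_DW > 0:
        hi = rec.GY / rec.above_ground_DW
    else:
        hi = math.nan
        errors["harvest_index"] = "above-ground dry weight must be positive"
    return YieldSummary(fertility, sgw, hi, errors)


def percent_increase_gy(gy_line: float, gy_wt: float, decimals: int = 1) -> float:
    """Percent grain-yield increase of a line over wild type.

    100 * (gy_line - gy_wt) / gy_wt, rounded half-to-even to ``decimals``.
    """
    if gy_wt <= 0:
        raise DataError("wild-type grain yield must be positive")
    return round(100.0 * (gy_line - gy_wt) / gy_wt, decimals)
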