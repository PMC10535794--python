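"""Deterministic dietary risk chain: EDI, EWI, THQ, HI, CR and TCR.

The chain models chronic dietary exposure of an adult consumer of farmed
rainbow trout.  For element *i* with mean muscle concentration ``C_i``
(mg/kg wet weight):

    EDI_i = C_i * IR * EF * ED / (BW * AT) * ADAF * ARm_i      [mg/kg-bw/day]
    EWI_i = 7 * EDI_i                                          [mg/kg-bw/week]
    THQ_i = EF * ED * FIR * C_i * 1e-3 / (RfD_i * BW * AT)     [-]
    HI    = sum_i THQ_i                                        [-]
    CR_i  = EF * ED * CSF_i * EDI_i / AT * 1e-3  (as printed)  [-]
    TCR   = sum_i CR_i                                         [-]

With the default averaging time AT = EF * ED (chronic exposure over the whole
duration) the EF*ED/AT factors cancel, so EDI reduces to C*IR/BW*ADAF*ARm and
THQ to FIR*1e-3*C/(RfD*BW).  The 1e-3 in THQ is the g -> kg conversion of the
fish ingestion rate FIR (g/person/day).  The 1e-3 in CR has no such dimensional
reading; it is applied verbatim in the default ``as_printed`` mode, and an
``unscaled`` mode omitting it is provided because the factor changes TCR by
three orders of magnitude (see docs/methods.md).

THQ or HI above 1 flags potential non-carcinogenic effects over a lifetime;
TCR is judged against the conventional acceptability band 1e-6 to 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ELEMENTS
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ExposureParams",
    "ToxicityParams",
    "RiskResult",
    "edi",
    "ewi",
    "thq",
    "hazard_index",
    "cancer_risk",
    "total_cancer_risk",
    "classify_tcr",
    "assess_sector",
    "risk_table",
    "CR_MODES",
    "ACCEPTABLE_TCR_BAND",
]

CR_MODES = ("as_printed", "unscaled")

#: Conventional carcinogenic-risk acceptability band (closed at both ends).
ACCEPTABLE_TCR_BAND = (1e-6, 1e-4)


def _default_arm() -> dict[str, float]:
    return {sym: info.arm for sym, info in ELEMENTS.items()}


@dataclass
class ExposureParams:
    """Adult dietary exposure constants.

    Defaults: ingestion rate 0.34 kg/person/day (FIR 340 g/day), exposure
    frequency 365 days/year over a 74.8-year expected lifetime, 60 kg body
    weight, adult age adjustment factor 1, and averaging time EF*ED days.
    Absorption efficiencies (``arm``): Pb 33%, As 75%, others 100%.
    """

    ir: float = 0.34  # kg/person/day
    ef: float = 365.0  # days/year
    ed: float = 74.8  # years
    bw: float = 60.0  # kg
    adaf: float = 1.0
    fir_g_per_day: float = 340.0  # g/person/day, THQ path
    at: float | None = None  # days; defaults to ef * ed
    arm: dict[str, float] = field(default_factory=_default_arm)

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "adaf", "fir_g_per_day"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"exposure parameter {name} must be positive")
        if self.at is not None and self.at <= 0:
            raise ConfigurationError("averaging time AT must be positive")
        for sym, a in self.arm.items():
            if not 0 < a <= 1:
                raise ConfigurationError(f"ARm for {sym} must be in (0, 1], got {a}")

    @property
    def resolved_at(self) -> float:
        return self.ef * self.ed if self.at is None else self.at

    def arm_for(self, element: str) -> float:
        return self.arm.get(element, 1.0)


@dataclass
class ToxicityParams:
    """Per-element oral reference doses and cancer slope factors."""

    rfd: dict[str, float] = field(
        default_factory=lambda: {sym: info.rfd for sym, info in ELEMENTS.items()}
    )
    csf: dict[str, float] = field(
        default_factory=lambda: {
            sym: info.csf for sym, info in ELEMENTS.items() if info.csf is not None
        }
    )

    def __post_init__(self) -> None:
        for sym, v in self.rfd.items():
            if v <= 0:
                raise ConfigurationError(f"RfD for {sym} must be positive")
        for sym, v in self.csf.items():
            if v <= 0:
                raise ConfigurationError(f"CSF for {sym} must be positive")

    @property
    def carcinogens(self) -> tuple[str, ...]:
        return tuple(sorted(self.csf))


def edi(mc: float, p: ExposureParams, element: str):
    """Estimated daily intake, mg per kg body weight per day.

    ``mc`` is the mean muscle concentration (mg/kg w/w).  Accepts scalars or
    numpy arrays for ``mc``.
    """
    if p.bw <= 0 or p.resolved_at <= 0:
        raise ConfigurationError("BW and AT must be positive")
    return mc * p.ir * p.ef * p.ed / (p.bw * p.resolved_at) * p.adaf * p.arm_for(element)


def ewi(edi_value: float):
    """Estimated weekly intake: 7 x EDI, mg per kg body weight per week."""
    if np.any(np.asarray(edi_value) < 0):
        raise ValidationError("EDI must be non-negative")
    return edi_value * 7


def thq(
    c: float,
    p: ExposureParams,
    t: ToxicityParams,
    element: str,
    fir_g_per_day: float | None = None,
):
    """Target hazard quotient for one element (dimensionless).

    ``fir_g_per_day`` overrides the exposure registry's fish ingestion rate.
    Raises if the element has no registered oral reference dose.
    """
    if element not in t.rfd:
        raise ConfigurationError(f"no RfD registered for element {element!r}")
    fir = p.fir_g_per_day if fir_g_per_day is None else fir_g_per_day
    if fir <= 0:
        raise ConfigurationError("fish ingestion rate must be positive")
    return p.ef * p.ed * fir * c * 1e-3 / (t.rfd[element] * p.bw * p.resolved_at)


def hazard_index(thq_by_element: Mapping[str, float]) -> tuple[float, bool]:
    """Hazard index: exact sum of the per-element THQs, plus the > 1 flag."""
    if not thq_by_element:
        raise ValidationError("hazard index requires at least one THQ")
    hi = float(sum(thq_by_element.values()))
    return hi, hi > 1.0


def cancer_risk(
    edi_value: float,
    csf: float,
    mode: str = "as_printed",
    p: ExposureParams | None = None,
):
    """Carcinogenic risk for one element from its EDI and slope factor.

    ``as_printed`` applies the published 1e-3 factor (CR = CSF * EDI * 1e-3 at
    the default averaging time); ``unscaled`` omits it (the textbook
    CR = CSF * EDI).  The mode used is recorded in downstream outputs.
    """
    if mode not in CR_MODES:
        raise ConfigurationError(f"unknown cancer-risk mode {mode!r}; use one of {CR_MODES}")
    if csf <= 0:
        raise ConfigurationError("CSF must be positive")
    p = p if p is not None else ExposureParams()
    scale = 1e-3 if mode == "as_printed" else 1.0
    return p.ef * p.ed * csf * edi_value / p.resolved_at * scale


def classify_tcr(tcr: float) -> str:
    """Place a total cancer risk relative to the closed [1e-6, 1e-4] band."""
    lo, hi = ACCEPTABLE_TCR_BAND
    if tcr < lo:
        return "below 1e-6"
    if tcr > hi:
        return "above 1e-4"
    return "within band"


def total_cancer_risk(cr_by_element: Mapping[str, float]) -> tuple[float, str]:
    """Total cancer risk: exact sum of per-carcinogen risks, plus its class."""
    if not cr_by_element:
        raise ValidationError("total cancer risk requires at least one CR")
    tcr = float(sum(cr_by_element.values()))
    return tcr, classify_tcr(tcr)


@dataclass(frozen=True)
class RiskResult:
    """Deterministic risk outputs for one sector."""

    sector: str
    edi: dict[str, float]  # mg/kg-bw/day
    ewi: dict[str, float]  # mg/kg-bw/week
    thq: dict[str, float]
    hi: float
    hi_exceeds: bool
    cr: dict[str, float]
    tcr: float
    tcr_class: str
    cr_mode: str


def assess_sector(
    sector: str,
    mean_concentrations: Mapping[str, float],
    exposure: ExposureParams | None = None,
    toxicity: ToxicityParams | None = None,
    cr_mode: str = "as_printed",
) -> RiskResult:
    """Run the full deterministic chain on one sector's mean concentrations.

    ``mean_concentrations`` maps element symbol to mean muscle concentration
    (mg/kg w/w).  THQ/HI cover every element given; CR/TCR cover the
    registered carcinogens among them.
    """
    exposure = exposure if exposure is not None else ExposureParams()
    toxicity = toxicity if toxicity is not None else ToxicityParams()

    edi_d: dict[str, float] = {}
    thq_d: dict[str, float] = {}
    cr_d: dict[str, float] = {}
    for element, mc in mean_concentrations.items():
        if mc < 0:
            raise ValidationError(f"negative mean concentration for {element}")
        edi_d[element] = float(edi(mc, exposure, element))
        thq_d[element] = float(thq(mc, exposure, toxicity, element))
        if element in toxicity.csf:
            cr_d[element] = float(
                cancer_risk(edi_d[element], toxicity.csf[element], cr_mode, exposure)
            )
    hi, flag = hazard_index(thq_d)
    tcr, tcr_class = total_cancer_risk(cr_d) if cr_d else (0.0, classify_tcr(0.0))
    return RiskResult(
        sector=sector,
        edi=edi_d,
        ewi={k: float(ewi(v)) for k, v in edi_d.items()},
        thq=thq_d,
        hi=hi,
        hi_exceeds=flag,
        cr=cr_d,
        tcr=tcr,
        tcr_class=tcr_class,
        cr_mode=cr_mode,
    )


def risk_table(results: list[RiskResult]) -> pd.DataFrame:
    """Hazard/cancer-risk table, one row per sector.

    Columns mirror the conventional survey layout: THQ per element (Cu, Pb,
    Zn, As order), HI, then CR per carcinogen, TCR and its classification.
    """
    element_order = [e for e in ("Cu", "Pb", "Zn", "As") if any(e in r.thq for r in results)]
    extra = sorted({e for r in results for e in r.thq} - set(element_order))
    rows = []
    for r in results:
        row: dict[str, object] = {"sector": r.sector}
        for e in element_order + extra:
            row[f"THQ-{e}"] = r.thq.get(e)
        row["HI"] = r.hi
        row["HI>1"] = r.hi_exceeds
        for e in sorted(r.cr):
            row[f"CR-{e}"] = r.cr[e]
        row["TCR"] = r.tcr
        row["TCR_class"] = r.tcr_class
        row["cr_mode"] = r.cr_mode
        rows.append(row)
    return pd.DataFrame(rows)
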