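"""Bioconcentration (BCF) and biosediment accumulation (BSAF) factors.

BCF = C_organism / C_water measures uptake from the dissolved phase; it mixes
mg/kg over mg/L and is reported as a dimensionless ratio under the usual
L/kg convention.  BSAF = C_organism / C_sediment measures the organism's
capacity to concentrate a metal relative to the sediment it lives over.

Ratios are formed per replicate pair — the muscle sample and the water (or
sediment) sample with the same ``replicate_id`` within a sector — and
summarised by their median.  The median of per-pair ratios and the ratio of
medians are different statistics in general; both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Matrix
from .errors import PairingError, ValidationError

__all__ = ["bcf", "bsaf", "FactorResult", "factor_profile"]

_DENOMINATOR = {"BCF": Matrix.WATER, "BSAF": Matrix.SEDIMENT}


def bcf(c_organism: float, c_water: float) -> float:
    """Bioconcentration factor: organism concentration over water concentration.

    Parameters are in mg/kg (organism) and mg/L (water); the quotient is
    returned as a plain ratio.  ``c_water`` must be strictly positive — a
    zero or negative denominator raises rather than returning infinity.
    """
    if c_water <= 0:
        raise ValidationError(f"water concentration must be > 0, got {c_water}")
    if c_organism < 0:
        raise ValidationError(f"organism concentration must be >= 0, got {c_organism}")
    return c_organism / c_water


def bsaf(c_organism: float, c_sediment: float) -> float:
    """Biosediment accumulation factor: organism over sediment concentration."""
    if c_sediment <= 0:
        raise ValidationError(f"sediment concentration must be > 0, got {c_sediment}")
    if c_organism < 0:
        raise ValidationError(f"organism concentration must be >= 0, got {c_organism}")
    return c_organism / c_sediment


@dataclass(frozen=True)
class FactorResult:
    """Per-(sector, element) accumulation-factor profile."""

    sector: str
    element: str
    kind: str  # "BCF" or "BSAF"
    per_pair_values: tuple[float, ...]
    median: float
    ratio_of_medians: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_pair_values):
            raise ValidationError("accumulation factors must be non-negative")


def factor_profile(frame: pd.DataFrame, kind: str) -> list[FactorResult]:
    """Compute per-pair BCF or BSAF profiles for every (sector, element).

    Pairs the muscle record with the water (BCF) or sediment (BSAF) record
    sharing its ``replicate_id`` within each sector; an orphan replicate on
    either side is an error naming the orphan.  One ratio per pair; the
    summary median is taken over the pairs.
    """
    if kind not in _DENOMINATOR:
        raise ValidationError(f"kind must be 'BCF' or 'BSAF', got {kind!r}")
    denom_matrix = _DENOMINATOR[kind].value

    num = frame[frame["matrix"] == Matrix.MUSCLE.value]
    den = frame[frame["matrix"] == denom_matrix]
    merged = num.merge(
        den,
        on=["sector", "element", "replicate_id"],
        how="outer",
        suffixes=("_muscle", "_denom"),
        indicator=True,
    )
    orphans = merged[merged["_merge"] != "both"]
    if not orphans.empty:
        o = orphans.iloc[0]
        side = "muscle" if o["_merge"] == "left_only" else denom_matrix
        raise PairingError(
            f"unpaired replicate: sector={o['sector']} element={o['element']} "
            f"replicate_id={o['replicate_id']} present only in {side}"
        )

    results: list[FactorResult] = []
    for (sector, element), grp in merged.groupby(["sector", "element"], sort=True):
        c_org = grp["concentration_muscle"].to_numpy(float)
        c_den = grp["concentration_denom"].to_numpy(float)
        if np.any(c_den <= 0):
            raise ValidationError(
                f"non-positive {denom_matrix} concentration in sector {sector}, "
                f"element {element}: ratio undefined"
            )
        ratios = c_org / c_den
        results.append(
            FactorResult(
                sector=str(sector),
                element=str(element),
                kind=kind,
                per_pair_values=tuple(ratios),
                median=float(np.median(ratios)),
                ratio_of_medians=float(np.median(c_org) / np.median(c_den)),
            )
        )
    return results


def factors_summary_frame(results: list[FactorResult]) -> pd.DataFrame:
    """Summary table: sector, element, kind, n_pairs, median, min, max."""
    return pd.DataFrame(
        {
            "sector": [r.sector for r in results],
            "element": [r.element for r in results],
            "kind": [r.kind for r in results],
            "n_pairs": [len(r.per_pair_values) for r in results],
            "median": [r.median for r in results],
            "min": [min(r.per_pair_values) for r in results],
            "max": [max(r.per_pair_values) for r in results],
            "ratio_of_medians": [r.ratio_of_medians for r in results],
        }
    )


def factors_long_frame(results: list[FactorResult]) -> pd.DataFrame:
    """Long-format per-pair values, ready for plotting."""
    rows = [
        {"sector": r.sector, "element": r.element, "kind": r.kind, "pair_index": i + 1, "value": v}
        for r in results
        for i, v in enumerate(r.per_pair_values)
    ]
    return pd.DataFrame(rows)
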