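"""Synthetic concentration datasets emulating the survey design.

The generator reproduces the study layout — 3 river sectors x 3 matrices
(muscle, water, sediment) x 4 elements (As, Cu, Pb, Zn) x 12 replicates —
with each cell drawn from a positive distribution calibrated to the survey's
published central value and dispersion (:mod:`troutrisk.study`).  The default
family is lognormal (concentrations are positive and right-skewed, and the
survey data were non-normal); a zero-truncated normal is available for
sensitivity work.  The printed "±" dispersion is treated as a standard
deviation.

Draws come from one seeded generator in a fixed cell order (sector upper,
middle, lower; matrix muscle, water, sediment; element alphabetical), so a
seed fully determines the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ELEMENTS, Matrix, lookup_guideline, validate_concentrations
from .errors import ConfigurationError, ValidationError
from .montecarlo import FAMILIES, DistributionSpec
from .study import SURVEY_CONCENTRATIONS

__all__ = ["GeneratorConfig", "generate", "inject_exceedance_pattern"]

_SECTOR_ORDER = ("upper", "middle", "lower")
_MATRIX_ORDER = (Matrix.MUSCLE, Matrix.WATER, Matrix.SEDIMENT)


def _default_targets() -> dict[tuple[str, str, str], tuple[float, float]]:
    return dict(SURVEY_CONCENTRATIONS)


@dataclass
class GeneratorConfig:
    """Targets and sampling settings for the synthetic dataset.

    ``targets`` maps ``(sector, matrix, element)`` to ``(central, dispersion)``
    in matrix units; defaults are the published survey values.
    """

    targets: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=_default_targets
    )
    family: str = "lognormal"
    n_replicates: int = 12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; use one of {FAMILIES}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for cell, (central, spread) in self.targets.items():
            if central <= 0 or spread < 0:
                raise ConfigurationError(
                    f"invalid target for cell {cell}: central must be > 0, dispersion >= 0"
                )


def generate(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a validated synthetic concentration dataset.

    Returns the canonical tidy table with ``len(targets) * n_replicates``
    rows (432 at the survey design: 3 sectors x 3 matrices x 4 elements x 12).
    """
    config = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    def cell_key(cell: tuple[str, str, str]) -> tuple[int, int, str]:
        sector, matrix, element = cell
        return (_SECTOR_ORDER.index(sector), _MATRIX_ORDER.index(Matrix(matrix)), element)

    rows = []
    for cell in sorted(config.targets, key=cell_key):
        sector, matrix, element = cell
        if element not in ELEMENTS:
            raise ConfigurationError(f"unknown element in target cell {cell}")
        central, spread = config.targets[cell]
        spec = DistributionSpec(element=element, family=config.family, mean=central, sd=spread)
        draws = spec.sample(rng, config.n_replicates)
        for rep, value in enumerate(draws, start=1):
            rows.append(
                {
                    "sector": sector,
                    "matrix": matrix,
                    "element": element,
                    "replicate_id": rep,
                    "concentration": float(value),
                }
            )
    return validate_concentrations(pd.DataFrame(rows))


def inject_exceedance_pattern(
    frame: pd.DataFrame,
    pattern: set[tuple[str, str, str | None]],
    margin: float = 1.2,
) -> pd.DataFrame:
    """Shift selected cells so their median exceeds the registered maximum limit.

    ``pattern`` holds ``(matrix, element, sector)`` cells (sector ``None``
    means all three sectors).  A listed cell whose median already exceeds the
    limit is left untouched; otherwise the cell is scaled by the minimum
    multiplicative factor that lifts its median strictly above
    ``margin * ML``, preserving its shape.  The operation is idempotent.
    """
    out = frame.copy()
    for matrix, element, sector in pattern:
        sectors = _SECTOR_ORDER if sector is None else (sector,)
        for sec in sectors:
            mask = (
                (out["matrix"] == Matrix(matrix).value)
                & (out["element"] == element)
                & (out["sector"] == sec)
            )
            if not mask.any():
                raise ValidationError(
                    f"pattern cell not present in dataset: ({matrix}, {element}, {sec})"
                )
            ml = lookup_guideline(matrix, element).value
            med = float(out.loc[mask, "concentration"].median())
            if med > ml:
                continue
            if med <= 0:
                raise ValidationError(
                    f"cannot shift cell ({matrix}, {element}, {sec}) with zero median"
                )
            factor = margin * ml / med * (1 + 1e-9)  # strictly above margin * ML
            out.loc[mask, "concentration"] *= factor
    return out
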