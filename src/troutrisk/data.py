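"""Domain types, units discipline, and CSV I/O for concentration datasets.

A concentration dataset is a tidy :class:`pandas.DataFrame` with one row per
``(sector, matrix, element, replicate_id)`` and a ``concentration`` column in
the units fixed by the matrix: mg/kg wet weight for trout muscle, mg/L for
water, mg/kg (as reported) for sediment.  Cross-matrix arithmetic is never
performed implicitly; ratio operations live in :mod:`troutrisk.bioaccumulation`.

The module also carries the element registry (with the toxicological constants
each element needs downstream) and the built-in regulatory maximum limits
(FAO/WHO and FSANZ for fish muscle, USEPA for water, Canadian interim sediment
quality guidelines for sediment).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyGroupError, ValidationError

__all__ = [
    "Matrix",
    "ElementInfo",
    "ELEMENTS",
    "register_element",
    "SECTORS",
    "ConcentrationRecord",
    "GuidelineLimit",
    "DATASET_COLUMNS",
    "validate_concentrations",
    "read_concentrations",
    "write_concentrations",
    "builtin_guidelines",
    "guidelines_frame",
    "lookup_guideline",
    "summarize",
]

SECTORS: tuple[str, ...] = ("upper", "middle", "lower")

DATASET_COLUMNS = ("sector", "matrix", "element", "replicate_id", "concentration")


class Matrix(str, enum.Enum):
    """Sampled matrix; fixes the concentration units."""

    MUSCLE = "muscle"
    WATER = "water"
    SEDIMENT = "sediment"

    @property
    def units(self) -> str:
        return _MATRIX_UNITS[self]


_MATRIX_UNITS = {
    Matrix.MUSCLE: "mg/kg w/w",
    Matrix.WATER: "mg/L",
    # dry- vs wet-weight basis is not specified upstream; carried as reported
    Matrix.SEDIMENT: "mg/kg (as reported)",
}


@dataclass(frozen=True)
class ElementInfo:
    """An element plus the toxicological constants the risk chain needs.

    Parameters
    ----------
    symbol
        Chemical symbol, e.g. ``"Pb"``.
    rfd
        Oral reference dose, mg per kg body weight per day (USEPA IRIS).
    arm
        Gastrointestinal absorption efficiency, fraction in (0, 1].
    csf
        Cancer slope factor, (mg/kg-day)^-1, or ``None`` for
        non-carcinogens (by the oral route, for the elements handled here).
    """

    symbol: str
    rfd: float
    arm: float = 1.0
    csf: float | None = None

    @property
    def carcinogen(self) -> bool:
        return self.csf is not None

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise ConfigurationError(f"RfD for {self.symbol} must be positive")
        if not 0 < self.arm <= 1:
            raise ConfigurationError(f"ARm for {self.symbol} must be in (0, 1]")
        if self.csf is not None and self.csf <= 0:
            raise ConfigurationError(f"CSF for {self.symbol} must be positive")


#: Registry of known elements.  RfDs are USEPA IRIS oral reference doses;
#: absorption efficiencies: Pb 33%, As 75%, essential metals 100%.
ELEMENTS: dict[str, ElementInfo] = {
    "As": ElementInfo("As", rfd=3e-4, arm=0.75, csf=1.5),
    "Cu": ElementInfo("Cu", rfd=4e-2),
    "Pb": ElementInfo("Pb", rfd=3.5e-3, arm=0.33, csf=0.0085),
    "Zn": ElementInfo("Zn", rfd=3e-1),
}


def register_element(symbol: str, *, rfd: float, arm: float = 1.0, csf: float | None = None) -> ElementInfo:
    """Register a new element; full toxicity parameters are mandatory.

    Datasets mentioning a symbol absent from the registry are rejected at
    ingest, so extending the analysis to e.g. Cd requires registering it with
    its RfD (and CSF if carcinogenic) first.
    """
    if symbol in ELEMENTS:
        raise ConfigurationError(f"element {symbol!r} is already registered")
    info = ElementInfo(symbol, rfd=rfd, arm=arm, csf=csf)
    ELEMENTS[symbol] = info
    return info


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured concentration in one sector/matrix/element/replicate."""

    sector: str
    matrix: Matrix
    element: str
    replicate_id: int
    concentration: float

    @property
    def units(self) -> str:
        return self.matrix.units


@dataclass(frozen=True)
class GuidelineLimit:
    """A regulatory maximum limit (ML) for one matrix and element."""

    matrix: Matrix
    element: str
    value: float
    source: str

    @property
    def units(self) -> str:
        return self.matrix.units

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(
                f"guideline limit for {self.element} in {self.matrix.value} must be positive"
            )


def validate_concentrations(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy concentration table and normalise its dtypes.

    Checks, naming the offending row (0-based data row) on failure:

    * all of ``sector, matrix, element, replicate_id, concentration`` present;
    * sector in {upper, middle, lower}; matrix in {muscle, water, sediment};
      element in the registry;
    * replicate_id an integer >= 1;
    * concentration a non-negative finite number (non-detects are rejected:
      encode a measured zero as 0, never as a blank);
    * ``(sector, matrix, element, replicate_id)`` unique.
    """
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    out = frame.loc[:, list(DATASET_COLUMNS)].copy().reset_index(drop=True)

    def _first_bad(mask: pd.Series, message: str) -> None:
        if mask.any():
            i = int(np.flatnonzero(mask.to_numpy())[0])
            raise ValidationError(f"row {i}: {message}: {out.iloc[i].to_dict()}")

    _first_bad(~out["sector"].isin(SECTORS), "unknown sector")
    _first_bad(~out["matrix"].isin([m.value for m in Matrix]), "unknown matrix")
    _first_bad(~out["element"].isin(ELEMENTS), "unknown element")

    rid = pd.to_numeric(out["replicate_id"], errors="coerce")
    _first_bad(rid.isna() | (rid != rid.round()) | (rid < 1),
               "replicate_id must be an integer >= 1")
    conc = pd.to_numeric(out["concentration"], errors="coerce")
    _first_bad(conc.isna() | ~np.isfinite(conc),
               "missing or non-finite concentration (non-detects are rejected)")
    _first_bad(conc < 0, "negative concentration")

    out["replicate_id"] = rid.astype(int)
    out["concentration"] = conc.astype(float)

    key = ["sector", "matrix", "element", "replicate_id"]
    dup = out.duplicated(subset=key)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {i}: duplicate key {tuple(out.loc[i, key])}"
        )
    return out


def read_concentrations(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a concentration CSV.

    ``schema`` maps canonical column names to the file's column names, e.g.
    ``{"concentration": "value_mgkg"}`` for a file with a renamed column.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    frame = pd.read_csv(path)
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        frame = frame.rename(columns=rename)
    return validate_concentrations(frame)


def write_concentrations(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a concentration table as the canonical CSV (full precision)."""
    validate_concentrations(frame).to_csv(path, index=False)


def builtin_guidelines() -> tuple[GuidelineLimit, ...]:
    """The registered maximum limits: 3 matrices x 4 elements.

    Muscle limits follow FAO/WHO (Codex) except As (FSANZ); water limits are
    USEPA national recommended criteria; sediment limits are the Canadian
    interim sediment quality guidelines (ISQG).
    """
    M, W, S = Matrix.MUSCLE, Matrix.WATER, Matrix.SEDIMENT
    return (
        GuidelineLimit(M, "As", 2.0, "FSANZ"),
        GuidelineLimit(M, "Cu", 30.0, "FAO/WHO"),
        GuidelineLimit(M, "Pb", 0.3, "FAO/WHO"),
        GuidelineLimit(M, "Zn", 30.0, "FAO/WHO"),
        GuidelineLimit(W, "As", 0.01, "USEPA"),
        GuidelineLimit(W, "Cu", 1.3, "USEPA"),
        GuidelineLimit(W, "Pb", 0.015, "USEPA"),
        GuidelineLimit(W, "Zn", 5.0, "USEPA"),
        GuidelineLimit(S, "As", 5.9, "CEQG-ISQG"),
        GuidelineLimit(S, "Cu", 35.7, "CEQG-ISQG"),
        GuidelineLimit(S, "Pb", 35.0, "CEQG-ISQG"),
        GuidelineLimit(S, "Zn", 123.0, "CEQG-ISQG"),
    )


def guidelines_frame(limits: Iterable[GuidelineLimit] | None = None) -> pd.DataFrame:
    """Guideline table as a DataFrame (matrix, element, value, units, source)."""
    limits = tuple(limits) if limits is not None else builtin_guidelines()
    return pd.DataFrame(
        {
            "matrix": [g.matrix.value for g in limits],
            "element": [g.element for g in limits],
            "value": [g.value for g in limits],
            "units": [g.units for g in limits],
            "source": [g.source for g in limits],
        }
    )


def lookup_guideline(
    matrix: Matrix | str, element: str, limits: Iterable[GuidelineLimit] | None = None
) -> GuidelineLimit:
    """Return the maximum limit for (matrix, element)."""
    matrix = Matrix(matrix)
    limits = tuple(limits) if limits is not None else builtin_guidelines()
    for g in limits:
        if g.matrix is matrix and g.element == element:
            return g
    raise ConfigurationError(f"no guideline limit registered for {element} in {matrix.value}")


def summarize(
    frame: pd.DataFrame, by: tuple[str, ...] = ("sector", "matrix", "element")
) -> pd.DataFrame:
    """Per-group n, mean, sd and median of concentrations.

    The median uses the midpoint of the two central order statistics for even
    n; sd is the sample standard deviation (ddof=1, NaN for n=1).
    """
    if frame.empty:
        raise EmptyGroupError("cannot summarize an empty dataset")
    grouped = frame.groupby(list(by), observed=True)["concentration"]
    out = grouped.agg(n="size", mean="mean", sd="std", median="median").reset_index()
    if (out["n"] == 0).any():
        raise EmptyGroupError("empty group encountered in summary")
    return out
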