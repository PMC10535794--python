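"""Published reference values from the Tishgo River trout survey (La Oroya, Peru).

The survey sampled three river sectors (upper, middle, lower course) around a
discontinued smelting facility, with 12 replicates per sector in each of three
matrices: rainbow trout muscle (mg/kg wet weight), river water (mg/L), and
bottom sediment (mg/kg, as reported), for the elements As, Cu, Pb and Zn.

These tables serve two roles:

* default calibration targets for :mod:`troutrisk.synthetic` (central value and
  dispersion per cell), and
* published downstream results (hazard quotients per sector) used as inputs to
  internal-consistency checks such as HI = sum of THQs.

The dispersion column is the survey's printed "±" value, treated here as a
standard deviation (the survey does not state whether it is SD, SE or an IQR
half-width; see docs/methods.md).
"""

from __future__ import annotations

SECTORS = ("upper", "middle", "lower")

#: (sector, matrix, element) -> (central value, dispersion), matrix units.
SURVEY_CONCENTRATIONS: dict[tuple[str, str, str], tuple[float, float]] = {
    # muscle, mg/kg w/w
    ("lower", "muscle", "As"): (0.11, 0.03),
    ("lower", "muscle", "Cu"): (0.21, 0.11),
    ("lower", "muscle", "Pb"): (0.24, 0.05),
    ("lower", "muscle", "Zn"): (2.51, 0.08),
    ("middle", "muscle", "As"): (0.02, 0.01),
    ("middle", "muscle", "Cu"): (0.20, 0.11),
    ("middle", "muscle", "Pb"): (0.19, 0.05),
    ("middle", "muscle", "Zn"): (2.57, 0.09),
    ("upper", "muscle", "As"): (0.01, 0.003),
    ("upper", "muscle", "Cu"): (0.15, 0.15),
    ("upper", "muscle", "Pb"): (0.17, 0.04),
    ("upper", "muscle", "Zn"): (2.51, 0.07),
    # water, mg/L
    ("lower", "water", "As"): (0.03, 0.005),
    ("lower", "water", "Cu"): (0.02, 0.012),
    ("lower", "water", "Pb"): (0.03, 0.009),
    ("lower", "water", "Zn"): (0.05, 0.031),
    ("middle", "water", "As"): (0.02, 0.003),
    ("middle", "water", "Cu"): (0.02, 0.016),
    ("middle", "water", "Pb"): (0.03, 0.008),
    ("middle", "water", "Zn"): (0.07, 0.025),
    ("upper", "water", "As"): (0.01, 0.003),
    ("upper", "water", "Cu"): (0.02, 0.017),
    ("upper", "water", "Pb"): (0.03, 0.01),
    ("upper", "water", "Zn"): (0.06, 0.028),
    # sediment, mg/kg (as reported)
    ("lower", "sediment", "As"): (40.25, 3.66),
    ("lower", "sediment", "Cu"): (22.24, 2.32),
    ("lower", "sediment", "Pb"): (47.68, 9.97),
    ("lower", "sediment", "Zn"): (231.04, 39.08),
    ("middle", "sediment", "As"): (42.44, 3.41),
    ("middle", "sediment", "Cu"): (15.22, 1.41),
    ("middle", "sediment", "Pb"): (31.75, 2.92),
    ("middle", "sediment", "Zn"): (169.83, 14.54),
    ("upper", "sediment", "As"): (32.53, 2.74),
    ("upper", "sediment", "Cu"): (18.39, 2.85),
    ("upper", "sediment", "Zn"): (180.11, 24.3),
    ("upper", "sediment", "Pb"): (36.62, 7.2),
}

#: Published per-element target hazard quotients by sector (trout consumption).
SURVEY_THQ: dict[str, dict[str, float]] = {
    "lower": {"Cu": 0.0004, "Pb": 0.1954, "Zn": 0.0007, "As": 0.0299},
    "middle": {"Cu": 0.0004, "Pb": 0.1547, "Zn": 0.0007, "As": 0.0054},
    "upper": {"Cu": 0.0003, "Pb": 0.1384, "Zn": 0.0007, "As": 0.0027},
}

#: Published hazard index per sector (the survey's printed sums of THQs).
SURVEY_HI: dict[str, float] = {"lower": 0.2264, "middle": 0.1613, "upper": 0.1421}

#: Cells where the survey flags a significant exceedance of the maximum limit
#: (one-sample comparison of the 12 replicates against the registered ML).
SURVEY_ML_EXCEEDANCE_FLAGS: frozenset[tuple[str, str, str]] = frozenset(
    {
        ("lower", "water", "As"),
        ("middle", "water", "As"),
        ("lower", "water", "Pb"),
        ("middle", "water", "Pb"),
        ("upper", "water", "Pb"),
        ("lower", "sediment", "As"),
        ("middle", "sediment", "As"),
        ("upper", "sediment", "As"),
        ("lower", "sediment", "Pb"),
        ("upper", "sediment", "Pb"),
        ("lower", "sediment", "Zn"),
        ("middle", "sediment", "Zn"),
        ("upper", "sediment", "Zn"),
    }
)
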