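"""Monte Carlo propagation of concentration uncertainty through the risk chain.

Concentration uncertainty per carcinogen is described by a two-parameter
distribution fitted to the sample mean and standard deviation — a lognormal
via moment matching, or a normal truncated at zero parameterised by the
pre-truncation moments.  Each of ``n_draws`` scenarios draws one concentration
per element, maps it through EDI -> CR -> TCR, and the exceedance probability
of a total-cancer-risk threshold is estimated as the fraction of scenarios
above it, with binomial standard error sqrt(p(1-p)/n).

Draws are generated from a single seeded generator in element-major order
(elements sorted alphabetically; all draws for one element before the next),
so a configuration reproduces bit-identical results on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .risk import CR_MODES, ExposureParams, ToxicityParams, cancer_risk, edi

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "MCConfig",
    "MCResult",
    "fit_distribution",
    "simulate_tcr",
    "threshold_sweep",
]

FAMILIES = ("lognormal", "normal_truncated_at_zero")


@dataclass(frozen=True)
class DistributionSpec:
    """A non-negative concentration distribution fitted to (mean, sd).

    With ``sd == 0`` the distribution degenerates to a point mass at the mean.  The
    lognormal family matches the requested mean and sd exactly (moment
    matching); the truncated normal is parameterised by the pre-truncation
    mean and sd, so its realised moments sit slightly above the nominal ones
    when the mean is within a few sd of zero.
    """

    element: str
    family: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; use one of {FAMILIES}")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
        if self.mean < 0 or (self.family == "lognormal" and self.sd > 0 and self.mean <= 0):
            raise ValidationError("mean must be positive for a non-degenerate lognormal")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` non-negative concentrations."""
        if self.sd == 0:
            return np.full(n, self.mean)
        if self.family == "lognormal":
            sigma2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - sigma2 / 2
            return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        a = (0.0 - self.mean) / self.sd  # truncation at zero, in z units
        return stats.truncnorm.rvs(
            a, np.inf, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


def fit_distribution(mean: float, sd: float, family: str = "lognormal") -> DistributionSpec:
    """Fit a concentration distribution to a sample mean and sd."""
    return DistributionSpec(element="", family=family, mean=mean, sd=sd)


@dataclass(frozen=True)
class MCConfig:
    """Simulation settings: draw count, seed, TCR threshold, interval level."""

    n_draws: int = 10_000
    seed: int = 0
    threshold: float = 1e-4
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")
        if not 0 < self.confidence < 1:
            raise ConfigurationError("confidence must be in (0, 1)")
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")


@dataclass(frozen=True)
class MCResult:
    """Simulated total-cancer-risk distribution for one sector."""

    sector: str
    tcr_draws: np.ndarray
    cr_draws: dict[str, np.ndarray]
    exceedance_probability: float
    mc_se: float
    percentiles: dict[float, float]  # percentile level (0-100) -> TCR value
    config: MCConfig
    cr_mode: str

    @property
    def exceedance_percent(self) -> float:
        return 100.0 * self.exceedance_probability


def simulate_tcr(
    specs: dict[str, DistributionSpec],
    exposure: ExposureParams | None = None,
    toxicity: ToxicityParams | None = None,
    config: MCConfig | None = None,
    cr_mode: str = "as_printed",
    sector: str = "",
) -> MCResult:
    """Simulate the total-cancer-risk distribution for one sector.

    ``specs`` maps element symbols to concentration distributions and must
    cover every registered carcinogen in ``toxicity``; the risk chain is the
    deterministic one applied draw-wise.
    """
    exposure = exposure if exposure is not None else ExposureParams()
    toxicity = toxicity if toxicity is not None else ToxicityParams()
    config = config if config is not None else MCConfig()
    if cr_mode not in CR_MODES:
        raise ConfigurationError(f"unknown cancer-risk mode {cr_mode!r}")
    missing = [e for e in toxicity.carcinogens if e not in specs]
    if missing:
        raise ConfigurationError(
            f"missing distribution spec for carcinogen(s): {', '.join(missing)}"
        )

    rng = np.random.default_rng(config.seed)
    cr_draws: dict[str, np.ndarray] = {}
    # element-major draw order, elements sorted, for cross-platform determinism
    for element in sorted(specs):
        if element not in toxicity.csf:
            continue
        conc = specs[element].sample(rng, config.n_draws)
        edi_draws = edi(conc, exposure, element)
        cr_draws[element] = np.asarray(
            cancer_risk(edi_draws, toxicity.csf[element], cr_mode, exposure)
        )
    tcr = np.sum(list(cr_draws.values()), axis=0)

    p = float(np.mean(tcr > config.threshold))
    se = float(np.sqrt(p * (1 - p) / config.n_draws))
    alpha = 1 - config.confidence
    levels = (round(100 * alpha / 2, 6), 50.0, round(100 * (1 - alpha / 2), 6))
    percentiles = {lv: float(np.percentile(tcr, lv)) for lv in levels}
    return MCResult(
        sector=sector,
        tcr_draws=tcr,
        cr_draws=cr_draws,
        exceedance_probability=p,
        mc_se=se,
        percentiles=percentiles,
        config=config,
        cr_mode=cr_mode,
    )


def threshold_sweep(result: MCResult, thresholds: list[float]) -> pd.DataFrame:
    """Exceedance probability of each threshold in an ascending sweep.

    Thresholds must be positive and sorted ascending; the resulting curve is
    non-increasing by construction.
    """
    arr = np.asarray(thresholds, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise ValidationError("thresholds must be positive")
    if np.any(np.diff(arr) < 0):
        raise ValidationError("thresholds must be sorted ascending")
    n = result.tcr_draws.size
    probs = [float(np.mean(result.tcr_draws > t)) for t in arr]
    return pd.DataFrame(
        {
            "sector": result.sector,
            "cr_mode": result.cr_mode,
            "threshold": arr,
            "n_draws": n,
            "seed": result.config.seed,
            "exceedance_probability": probs,
            "mc_se": [float(np.sqrt(p * (1 - p) / n)) for p in probs],
        }
    )
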