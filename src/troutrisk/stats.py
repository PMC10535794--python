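"""Nonparametric battery: Kruskal-Wallis, one-sample Wilcoxon vs a maximum
limit, and the Spearman correlation matrix across matrix-element pairs.

Kruskal-Wallis compares the three river sectors per element; the Wilcoxon
signed-rank test asks whether a cell's 12 replicates sit above (or differ
from) the registered regulatory maximum limit; Spearman correlations relate
every matrix-element combination (e.g. As in muscle vs Pb in sediment) across
replicates pooled over sectors.

Wilcoxon p-values are exact for n <= 25 (after dropping zero differences).
scipy's exact method declines tied ranks, and ties are routine when comparing
against a round limit value, so the exact tail is computed here by dynamic
programming over the 2^n equiprobable sign assignments: doubling the midranks
makes them integers, and a subset-sum count over those weights gives the null
distribution of W+, ties included.  Above n = 25 the normal approximation
with tie correction is used (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import Matrix
from .errors import DegenerateDataError, PairingError, ValidationError

__all__ = [
    "TestResult",
    "CorrelationMatrix",
    "kruskal_wallis",
    "wilcoxon_vs_limit",
    "spearman_matrix",
    "bh_adjust",
]

ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 25

_MATRIX_LETTER = {Matrix.MUSCLE: "m", Matrix.WATER: "w", Matrix.SEDIMENT: "s"}


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    grouping: str
    alternative: str
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def kruskal_wallis(groups: list[np.ndarray | list[float]], grouping: str = "sector") -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H is tie-corrected; the p-value is from the chi-square distribution with
    k - 1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least two groups")
    sizes = tuple(len(g) for g in groups)
    if any(s < 1 for s in sizes) or sum(sizes) < 3:
        raise ValidationError("each group needs >= 1 value and >= 3 in total")
    h, p = sps.kruskal(*groups)
    return TestResult(
        name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n=sizes,
        grouping=grouping,
        alternative="two_sided",
        method="chi-square approximation, tie-corrected",
    )


def _exact_signed_rank_tails(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """P(W+ >= w_plus) and P(W+ <= w_plus) under the exact sign-flip null.

    ``ranks`` are the (possibly tied, hence half-integer) midranks of |d|.
    Doubled ranks are integers; a subset-sum DP counts, for every achievable
    doubled W+, how many of the 2^n sign assignments realise it.
    """
    weights = np.rint(2 * ranks).astype(np.int64)
    total = int(weights.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for w in weights:
        counts[w:] += counts[:-w].copy() if w else counts.copy()
    counts /= 2.0 ** len(weights)
    w2 = 2 * w_plus
    # tolerate float fuzz at the observed value
    ge = float(counts[int(np.ceil(w2 - 1e-9)):].sum())
    le = float(counts[: int(np.floor(w2 + 1e-9)) + 1].sum())
    return ge, le


def wilcoxon_vs_limit(
    values: np.ndarray | list[float],
    ml: float,
    alternative: str = "greater",
    grouping: str = "",
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of values against a maximum limit.

    Differences equal to the limit are dropped (Wilcoxon's zero rule); if all
    differences are zero the test is undefined and raises.  ``alternative``
    is ``"greater"`` (median exceeds the limit — the exceedance-flag
    convention) or ``"two_sided"``.  The reported statistic is W+, the sum of
    positive ranks.
    """
    if alternative not in ("greater", "two_sided", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    d = np.asarray(values, dtype=float) - ml
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all values equal the limit; signed-rank test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size

    if n <= EXACT_WILCOXON_MAX_N:
        p_ge, p_le = _exact_signed_rank_tails(ranks, w_plus)
        method = "exact (sign-flip enumeration)"
    else:
        mean = n * (n + 1) / 4
        # tie correction: subtract sum(t^3 - t)/48 from the null variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(tie_counts**3 - tie_counts) / 48
        z = (w_plus - mean) / np.sqrt(var)
        p_ge = float(sps.norm.sf(z))
        p_le = float(sps.norm.cdf(z))
        method = "normal approximation, tie-corrected"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_ge, p_le))
    return TestResult(
        name="wilcoxon_vs_limit",
        statistic=w_plus,
        p_value=p,
        n=(n,),
        grouping=grouping,
        alternative=alternative,
        method=method,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rho and p-values across matrix-element variables.

    Labels follow the ``<element>-<m|w|s>`` convention (muscle, water,
    sediment), e.g. ``As-m`` or ``Pb-s``.
    """

    labels: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        r = self.rho.to_numpy(float)
        if not np.allclose(r, r.T):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0) or np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValidationError("rho must have unit diagonal and |rho| <= 1")

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, rho, p) over the upper triangle."""
        rows = []
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if j <= i:
                    continue
                rows.append(
                    {"var1": a, "var2": b,
                     "rho": float(self.rho.iloc[i, j]), "p": float(self.p.iloc[i, j])}
                )
        return pd.DataFrame(rows)


def spearman_matrix(frame: pd.DataFrame, per_sector: bool = False):
    """Spearman correlation across all matrix-element pairs.

    Records are aligned by ``(sector, replicate_id)``; by default sectors are
    pooled (n = sectors x replicates) into a single matrix.  With
    ``per_sector=True`` a dict of per-sector matrices is returned instead.
    Any hole in the alignment (a variable missing a replicate) raises.
    """
    if per_sector:
        return {
            str(sector): spearman_matrix(sub, per_sector=False)
            for sector, sub in frame.groupby("sector", sort=True)
        }
    wide = frame.pivot_table(
        index=["sector", "replicate_id"],
        columns=["matrix", "element"],
        values="concentration",
    )
    if wide.isna().any().any():
        col = wide.columns[wide.isna().any()][0]
        raise PairingError(f"incomplete alignment for {col}: replicate missing")
    # fixed variable order: muscle, water, sediment; elements alphabetical
    cols = sorted(
        wide.columns,
        key=lambda c: (list(_MATRIX_LETTER).index(Matrix(c[0])), c[1]),
    )
    wide = wide.loc[:, cols]
    labels = tuple(f"{el}-{_MATRIX_LETTER[Matrix(mx)]}" for mx, el in wide.columns)
    if wide.shape[0] < 3:
        raise ValidationError("need at least 3 aligned replicates for correlations")
    rho, p = sps.spearmanr(wide.to_numpy(float))
    if np.isscalar(rho):  # spearmanr collapses the 2-variable case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    else:
        p = np.asarray(p, dtype=float)
        np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        labels=labels,
        rho=pd.DataFrame(rho, index=labels, columns=labels),
        p=pd.DataFrame(p, index=labels, columns=labels),
        n=wide.shape[0],
    )


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
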