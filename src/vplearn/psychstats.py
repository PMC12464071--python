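"""Learning quantification and group statistics.

Learning is quantified by the learning index

    LI = (threshold_post - threshold_pre) / threshold_pre,

negative values meaning improvement.  Subjects whose training-location LI is
weaker than the criterion (default -0.20, i.e. less than 20% improvement) are
excluded.  Group comparisons use Welch's t-test with pooled-SD Cohen's d;
correlations use the Pearson t-test, and the two groups' transfer-LI
correlations are compared with Fisher's r-to-z test whose effect size is
Cohen's q = |atanh(r1) - atanh(r2)|.  Training curves are summarized with a
three-parameter power law T(b) = a * b**(-beta) + c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "learning_index",
    "subject_table",
    "learning_table",
    "apply_exclusions",
    "power_law_fit",
    "PowerLawFit",
    "welch_t",
    "WelchResult",
    "pearson_r_test",
    "PearsonResult",
    "compare_independent_correlations",
    "CorrelationComparison",
    "partial_eta_sq",
]


def learning_index(pre: float, post: float) -> float:
    """(post - pre) / pre; scale-invariant, negative = improvement."""
    if not pre > 0:
        raise ValueError(f"pre-threshold must be positive, got {pre}")
    return (post - pre) / pre


def subject_table(blocks: pd.DataFrame) -> pd.DataFrame:
    """Subject-level thresholds: mean over valid blocks per (time, location).

    ``blocks`` is the block-threshold table (columns ``subject``,
    ``randomization``, ``training_location``, ``time``, ``location``,
    ``block``, ``threshold``, ``valid``).  Invalid blocks are dropped before
    averaging, mirroring the discard rule for blocks with too few reversals.
    """
    ok = blocks[blocks["valid"].astype(bool)]
    out = (
        ok.groupby(
            ["subject", "randomization", "training_location", "time", "location"],
            as_index=False,
            observed=True,
        )["threshold"]
        .mean()
    )
    return out


def learning_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-subject LI at each location from the subject-level threshold table."""
    wide = subjects.pivot_table(
        index=["subject", "randomization", "training_location", "location"],
        columns="time",
        values="threshold",
        observed=True,
    ).reset_index()
    missing = wide["pre"].isna() | wide["post"].isna()
    wide = wide[~missing].copy()
    wide["li"] = [
        learning_index(pre, post) for pre, post in zip(wide["pre"], wide["post"])
    ]
    return wide[
        ["subject", "randomization", "training_location", "location", "pre", "post", "li"]
    ]


def apply_exclusions(
    learning: pd.DataFrame, criterion_li: float = -0.20
) -> tuple[pd.DataFrame, dict]:
    """Drop subjects whose training-location LI is weaker than ``criterion_li``.

    "Weaker" means LI > criterion (an LI of -0.10 is a 10% improvement and is
    excluded under the default -0.20 criterion).  Returns the retained rows
    and a report with per-group exclusion counts.
    """
    train = learning[learning["location"] == "training"]
    excluded_ids = set(train.loc[train["li"] > criterion_li, "subject"])
    retained = learning[~learning["subject"].isin(excluded_ids)].copy()
    report = {
        "criterion_li": criterion_li,
        "n_subjects": int(train["subject"].nunique()),
        "n_excluded": len(excluded_ids),
        "excluded_subjects": sorted(excluded_ids),
        "excluded_per_group": {
            str(g): int(
                train[
                    (train["randomization"] == g) & train["subject"].isin(excluded_ids)
                ]["subject"].nunique()
            )
            for g in train["randomization"].unique()
        },
    }
    return retained, report


@dataclass(frozen=True)
class PowerLawFit:
    a: float
    beta: float
    c: float
    residual: float  # L2 norm of residuals
    converged: bool


def power_law_fit(
    block_index: np.ndarray,
    thresholds: np.ndarray,
    with_offset: bool = True,
) -> PowerLawFit:
    """Least-squares fit of T(b) = a * b**(-beta) + c (c >= 0).

    ``with_offset=False`` selects the two-parameter variant (c = 0).
    Non-convergence is flagged in the result, not raised.
    """
    b = np.asarray(block_index, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    if b.size < 4:
        raise ValueError("need at least 4 blocks for a power-law fit")
    if np.any(t <= 0) or np.any(b <= 0):
        raise ValueError("block indices and thresholds must be positive")

    if with_offset:
        def model(x, a, beta, c):
            return a * x ** (-beta) + c

        c0 = max(float(t.min()) - 1e-6, 0.0)
        p0 = [max(float(t[0]) - c0, 1e-3), 0.5, c0]
        bounds = ([0.0, 0.0, 0.0], [np.inf, 10.0, np.inf])
    else:
        def model(x, a, beta):
            return a * x ** (-beta)

        p0 = [float(t[0]), 0.5]
        bounds = ([0.0, 0.0], [np.inf, 10.0])

    try:
        popt, _ = optimize.curve_fit(
            model, b, t, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
        converged = True
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
        converged = False
    resid = float(np.linalg.norm(t - model(b, *popt)))
    if with_offset:
        a, beta, c = popt
    else:
        (a, beta), c = popt, 0.0
    return PowerLawFit(float(a), float(beta), float(c), resid, converged)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    cohens_d: float


def welch_t(a, b) -> WelchResult:
    """Welch's two-sample t-test (a - b) with pooled-SD Cohen's d."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    s_pooled = math.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    d = (x.mean() - y.mean()) / s_pooled if s_pooled > 0 else float("nan")
    return WelchResult(float(t), float(df), float(p), float(d))


@dataclass(frozen=True)
class PearsonResult:
    r: float
    t: float
    df: int
    p: float
    sided: str


def pearson_r_test(x, y, sided: str = "two") -> PearsonResult:
    """Pearson correlation with t = r sqrt(n-2)/sqrt(1-r^2)."""
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    if abs(r) >= 1.0 - 1e-15:
        t = math.copysign(float("inf"), r)
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = stats.t.sf(abs(t), df)
        if sided == "two":
            p *= 2.0
    return PearsonResult(r, float(t), df, float(p), sided)


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p_value: float
    sidedness: str
    cohens_q: float


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int, sided: str = "one"
) -> CorrelationComparison:
    """Fisher r-to-z test for two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the one-sided
    alternative is r1 > r2.  Cohen's q is the absolute difference of the
    Fisher-transformed correlations.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"n must be > 3, got {n}")
    dz = math.atanh(r1) - math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = dz / se
    if sided == "one":
        p = stats.norm.sf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(
        r1, int(n1), r2, int(n2), float(z), float(p), sided, abs(dz)
    )


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared of an ANOVA term: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("require F >= 0 and positive degrees of freedom")
    return (F * df1) / (F * df1 + df2)
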