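"""Aligned rank transform (ART) factorial analysis of the threshold table.

The experiment is a split-plot design: each subject belongs to one
``randomization`` (phase/contrast) and one ``training_location`` (UVF/LVF)
group (between-subject factors) and contributes block-wise thresholds at
every combination of ``time`` (pre/post) and ``location`` (training,
C-transfer, F-transfer) (within-subject factors).

For each factorial term the response is *aligned* — the full-factorial cell
means are subtracted and the target term's effect estimate
(inclusion–exclusion over unweighted marginal means of the cell means) is
added back — then midranked, and a mixed ANOVA with a random subject
intercept is run on the ranks; only the target term is interpreted from its
own table.  Subject deviations are deliberately left in the aligned values:
they are the error stratum for between-subject terms.

The mixed ANOVA is computed by exact variance-stratum decomposition rather
than iterative REML: terms composed purely of between-subject factors are
tested on subject means against the subjects-within-groups stratum, and
terms involving a within-subject factor are tested in the subject-centered
stratum (ordinary least squares with subject indicators absorbed).  For
balanced compound-symmetric designs these F statistics and denominator
degrees of freedom coincide with the Satterthwaite values of the
random-intercept mixed model.  Post hoc contrasts use the ART-C
concatenate-and-align procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .psychstats import partial_eta_sq

__all__ = [
    "FACTORS",
    "FACTOR_LEVELS",
    "validate_cohort_table",
    "align_rank",
    "art_anova",
    "art_contrast",
    "ContrastResult",
    "headline_transfer_contrast",
]

FACTORS = ("time", "randomization", "location", "training_location")
FACTOR_LEVELS = {
    "time": ("pre", "post"),
    "randomization": ("phase", "contrast"),
    "location": ("training", "C-transfer", "F-transfer"),
    "training_location": ("UVF", "LVF"),
}


def validate_cohort_table(df: pd.DataFrame, response: str = "threshold") -> None:
    """Check factor levels, positive thresholds, and one group per subject."""
    if response not in df.columns:
        raise ValueError(f"missing response column {response!r}")
    if not np.all(np.asarray(df[response], dtype=float) > 0):
        raise ValueError("thresholds must be positive")
    for fac in FACTORS:
        if fac in df.columns:
            bad = set(df[fac].unique()) - set(FACTOR_LEVELS[fac])
            if bad:
                raise ValueError(f"unknown {fac} level(s): {sorted(bad)}")
    if "subject" in df.columns:
        for fac in ("randomization", "training_location"):
            if fac in df.columns:
                per = df.groupby("subject", observed=True)[fac].nunique()
                if (per > 1).any():
                    raise ValueError(f"subject with more than one {fac} level")


def _present_factors(df: pd.DataFrame) -> list[str]:
    return [f for f in FACTORS if f in df.columns and df[f].nunique() > 1]


def _subsets(term: tuple[str, ...]):
    for k in range(len(term) + 1):
        yield from itertools.combinations(term, k)


def _all_terms(factors) -> list[tuple[str, ...]]:
    factors = list(factors)
    return [
        t
        for k in range(1, len(factors) + 1)
        for t in itertools.combinations(factors, k)
    ]


class _Tab:
    """Integer-coded view of a cohort table, built once per analysis."""

    def __init__(self, df: pd.DataFrame, response: str):
        self.df = df
        self.n = len(df)
        self.y = np.asarray(df[response], dtype=float)
        self.present = _present_factors(df)
        self.codes: dict[str, np.ndarray] = {}
        self.n_levels: dict[str, int] = {}
        for f in self.present:
            levels = [l for l in FACTOR_LEVELS[f] if l in set(df[f])]
            self.codes[f] = df[f].map({l: i for i, l in enumerate(levels)}).to_numpy()
            self.n_levels[f] = len(levels)
        # full-factorial cell codes
        self.cell_code = self._combo_code(self.present)
        self.n_cells = int(self.cell_code.max()) + 1 if self.n else 0
        cnt = np.bincount(self.cell_code, minlength=self.n_cells)
        self.cell_mean = (
            np.bincount(self.cell_code, weights=self.y, minlength=self.n_cells)
            / np.maximum(cnt, 1)
        )
        self.has_subjects = False
        if "subject" in df.columns:
            self.subj_code, uniq = pd.factorize(df["subject"])
            self.n_subj = len(uniq)
            self.has_subjects = bool(
                np.bincount(self.subj_code).max() > 1
            )
        self.between: set[str] = set()
        if self.has_subjects:
            for f in self.present:
                first = {}
                const = True
                for s, c in zip(self.subj_code, self.codes[f]):
                    if s in first:
                        if first[s] != c:
                            const = False
                            break
                    else:
                        first[s] = c
                if const:
                    self.between.add(f)
        self._col_cache: dict[tuple[str, ...], np.ndarray] = {}

    def _combo_code(self, factors) -> np.ndarray:
        code = np.zeros(self.n, dtype=np.int64)
        for f in factors:
            code = code * self.n_levels[f] + self.codes[f]
        return code

    def aligned(self, term: tuple[str, ...]) -> np.ndarray:
        """Aligned response for ``term`` (residual + inclusion-exclusion
        effect estimate computed from unweighted marginal means of cell
        means)."""
        resid = self.y - self.cell_mean[self.cell_code]
        # cell-level codes for the margins
        cell_rows = {}  # one representative row per cell
        reps = np.zeros(self.n_cells, dtype=np.int64)
        reps[self.cell_code] = np.arange(self.n)
        est = np.zeros(self.n)
        for sub in _subsets(term):
            sign = (-1) ** (len(term) - len(sub))
            if not sub:
                est += sign * float(self.cell_mean.mean())
                continue
            sizes = [self.n_levels[f] for f in sub]
            cell_sub = np.zeros(self.n_cells, dtype=np.int64)
            row_sub = np.zeros(self.n, dtype=np.int64)
            for f in sub:
                cell_sub = cell_sub * self.n_levels[f] + self.codes[f][reps]
                row_sub = row_sub * self.n_levels[f] + self.codes[f]
            m = int(np.prod(sizes))
            marg = np.bincount(cell_sub, weights=self.cell_mean, minlength=m)
            marg /= np.maximum(np.bincount(cell_sub, minlength=m), 1)
            est += sign * marg[row_sub]
        return resid + est

    def term_columns(
        self, term: tuple[str, ...], codes: dict[str, np.ndarray] | None = None
    ) -> np.ndarray:
        """Sum-to-zero (center-coded) design columns for ``term``."""
        codes = codes if codes is not None else self.codes
        key = term
        if codes is self.codes and key in self._col_cache:
            return self._col_cache[key]
        out = None
        n = len(next(iter(codes.values())))
        for f in term:
            k = self.n_levels[f]
            mat = np.zeros((n, k - 1))
            c = codes[f]
            for j in range(k - 1):
                mat[c == j, j] = 1.0
            mat[c == k - 1, :] = -1.0
            out = mat if out is None else np.einsum(
                "ij,ik->ijk", out, mat
            ).reshape(n, -1)
        if codes is self.codes:
            self._col_cache[key] = out
        return out


def align_rank(
    df: pd.DataFrame, effect: tuple[str, ...] | list[str], response: str = "threshold"
) -> np.ndarray:
    """Aligned midranks of ``response`` for the target ``effect``.

    Alignment subtracts the full-factorial (fixed-effect) cell means and adds
    back the target term's effect, estimated by inclusion–exclusion over
    unweighted marginal means of the cell means so unbalanced replication
    does not leak other effects into the target.
    """
    effect = tuple(effect)
    tab = _Tab(df, response)
    if not effect or any(f not in tab.present for f in effect):
        raise ValueError(
            f"effect {effect} is not a subset of the table's factors {tab.present}"
        )
    return stats.rankdata(tab.aligned(effect))


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)


def _drop_f(X_parts: list[np.ndarray], drop_idx: int, y: np.ndarray):
    X_full = np.hstack(X_parts)
    sse_full, rank_full = _sse(X_full, y)
    X_red = np.hstack([m for i, m in enumerate(X_parts) if i != drop_idx])
    sse_red, rank_red = _sse(X_red, y)
    df1 = rank_full - rank_red
    df2 = len(y) - rank_full
    if df1 <= 0 or df2 <= 0 or sse_full <= 0:
        return float("nan"), max(df1, 0), max(df2, 0)
    F = max(((sse_red - sse_full) / df1) / (sse_full / df2), 0.0)
    return float(F), df1, df2


def _term_f(tab: _Tab, ranks: np.ndarray, term: tuple[str, ...]):
    """Wald-type F, df1, df2 and stratum label for one term on ranked data."""
    if not tab.has_subjects:
        terms = _all_terms(tab.present)
        parts = [np.ones((tab.n, 1))] + [tab.term_columns(t) for t in terms]
        F, df1, df2 = _drop_f(parts, terms.index(term) + 1, ranks)
        return F, df1, df2, "fixed"

    if set(term) <= tab.between:
        # subject-mean stratum
        cnt = np.bincount(tab.subj_code, minlength=tab.n_subj)
        ymean = np.bincount(tab.subj_code, weights=ranks, minlength=tab.n_subj) / cnt
        reps = np.zeros(tab.n_subj, dtype=np.int64)
        reps[tab.subj_code] = np.arange(tab.n)
        bfacs = sorted(tab.between, key=FACTORS.index)
        codes = {f: tab.codes[f][reps] for f in bfacs}
        bterms = _all_terms(bfacs)
        parts = [np.ones((tab.n_subj, 1))] + [
            tab.term_columns(t, codes) for t in bterms
        ]
        F, df1, df2 = _drop_f(parts, bterms.index(term) + 1, ymean)
        return F, df1, df2, "between-subjects"

    # within stratum: absorb subjects, keep every term with a within factor
    subj = np.zeros((tab.n, tab.n_subj))
    subj[np.arange(tab.n), tab.subj_code] = 1.0
    wterms = [t for t in _all_terms(tab.present) if not set(t) <= tab.between]
    parts = [subj] + [tab.term_columns(t) for t in wterms]
    F, df1, df2 = _drop_f(parts, wterms.index(term) + 1, ranks)
    return F, df1, df2, "within-subjects"


def art_anova(df: pd.DataFrame, response: str = "threshold") -> pd.DataFrame:
    """Full ART ANOVA table: one aligned-rank fit per factorial term.

    Returns a DataFrame with columns ``term, F, df1, df2, p, eta2p, stratum``.
    No multiplicity correction is applied across terms.
    """
    validate_cohort_table(df, response)
    tab = _Tab(df, response)
    if not tab.present:
        raise ValueError("no factors with >= 2 levels in table")
    rows = []
    for term in _all_terms(tab.present):
        ranks = stats.rankdata(tab.aligned(term))
        F, df1, df2, stratum = _term_f(tab, ranks, term)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else float("nan")
        eta = partial_eta_sq(F, df1, df2) if np.isfinite(F) and F >= 0 else float("nan")
        rows.append(
            {
                "term": ":".join(term),
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "eta2p": eta,
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastResult:
    estimate: float  # on the rank scale
    t: float
    df: float
    p: float
    cohens_d: float
    factors: tuple[str, ...]


def art_contrast(
    df: pd.DataFrame,
    factors: tuple[str, ...] | list[str],
    weights: dict[tuple, float],
    response: str = "threshold",
) -> ContrastResult:
    """ART-C post hoc contrast over the cells of ``factors``.

    The response is aligned to the cell means of the factor combination of
    interest (concatenate-and-align), midranked, and the weighted combination
    of estimated cell means is tested with subject indicators absorbed when a
    within-subject factor is involved.  ``weights`` maps level tuples (in
    ``factors`` order; plain level for a single factor) to weights that must
    sum to zero.  Cohen's d is derived from the t statistic as 2t/sqrt(df).
    """
    factors = tuple(factors)
    present = _present_factors(df)
    if any(f not in present for f in factors):
        raise ValueError(f"factors {factors} not all present in table")
    keys = {k if isinstance(k, tuple) else (k,) for k in weights}
    valid_levels = set(itertools.product(*[FACTOR_LEVELS[f] for f in factors]))
    if not keys <= valid_levels:
        raise ValueError(f"contrast names nonexistent cells: {keys - valid_levels}")
    if abs(sum(weights.values())) > 1e-9:
        raise ValueError("contrast weights must sum to zero")

    y = np.asarray(df[response], dtype=float)
    cell_mean = df.groupby(list(present), observed=True)[response].transform("mean")
    ucell = df.groupby(list(factors), observed=True)[response].transform("mean")
    ranks = stats.rankdata(y - np.asarray(cell_mean) + np.asarray(ucell))

    tab = _Tab(df, response)
    within_involved = tab.has_subjects and not set(factors) <= tab.between

    work = df.assign(_r=ranks)
    if tab.has_subjects and not within_involved:
        work = work.groupby(
            ["subject"] + list(factors), as_index=False, observed=True
        )["_r"].mean()

    cell_key = work[list(factors)].apply(tuple, axis=1)
    cell_names = sorted(cell_key.unique())
    codes = cell_key.map({c: i for i, c in enumerate(cell_names)}).to_numpy()
    cell_dummies = np.zeros((len(work), len(cell_names)))
    cell_dummies[np.arange(len(work)), codes] = 1.0
    if within_involved:
        subj = pd.get_dummies(work["subject"]).to_numpy(dtype=float)
        X = np.hstack([subj, cell_dummies])
        offset = subj.shape[1]
    else:
        X = cell_dummies
        offset = 0

    yv = work["_r"].to_numpy(dtype=float)
    XtX = X.T @ X
    pinv = np.linalg.pinv(XtX)
    beta = pinv @ (X.T @ yv)
    rank_X = int(np.linalg.matrix_rank(X))
    dof = len(yv) - rank_X
    sse = float((yv - X @ beta) @ (yv - X @ beta))
    sigma2 = sse / dof if dof > 0 else float("nan")

    c = np.zeros(X.shape[1])
    for levels, w in weights.items():
        lv = levels if isinstance(levels, tuple) else (levels,)
        try:
            j = cell_names.index(lv)
        except ValueError as exc:
            raise ValueError(f"no data in contrast cell {lv}") from exc
        c[offset + j] = w
    est = float(c @ beta)
    var = sigma2 * float(c @ pinv @ c)
    if var <= 0 or dof <= 0:
        raise ValueError("contrast is not estimable on this table")
    t = est / np.sqrt(var)
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    d = 2.0 * t / np.sqrt(dof)
    return ContrastResult(est, float(t), float(dof), p, float(d), factors)


def headline_transfer_contrast(
    df: pd.DataFrame, response: str = "threshold"
) -> ContrastResult:
    """Pre-post difference at the F-transfer location, phase minus contrast.

    Positive estimates mean the phase-randomized group improved more at the
    far transfer location than the contrast-randomized group.
    """
    weights = {
        ("pre", "F-transfer", "phase"): 1.0,
        ("post", "F-transfer", "phase"): -1.0,
        ("pre", "F-transfer", "contrast"): -1.0,
        ("post", "F-transfer", "contrast"): 1.0,
    }
    return art_contrast(df, ("time", "location", "randomization"), weights, response)
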