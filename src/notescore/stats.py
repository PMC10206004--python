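"""Reliability and validity statistics for note-based treatment scores.

Implements the validation battery used to qualify the note-based score:
Krippendorff's alpha with an ordinal difference metric (tolerating missing
cells), ICC(2,k) from the two-way random-effects ANOVA decomposition, per
category Dice agreement, Spearman rank correlation, bias-corrected and
accelerated (BCa) bootstrap confidence intervals, responder rate tables,
and a baseline-category multinomial logit with type-II likelihood-ratio
tests for covariate effects.

Rating conventions: values are the score codes {0 (N/A), 0.5 (intolerant),
1, 2, 3}.  For alpha, the 0/0.5 side codes count as missing; for the ICC
they are dropped listwise; only 1-3 enter ordinal statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "InsufficientDataError",
    "DegenerateStatisticError",
    "ReliabilityReport",
    "BootstrapResult",
    "round_half_up",
    "krippendorff_alpha",
    "icc_2k",
    "dice_per_category",
    "spearman_rho",
    "bootstrap_ci_bca",
    "responder_rate_table",
    "fit_multinomial_logit",
]

NA_CODES = (0.0, 0.5)


class InsufficientDataError(ValueError):
    """Too few usable units for the requested statistic."""


class DegenerateStatisticError(ValueError):
    """The statistic is undefined on the supplied data."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention used in printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    lower: float
    upper: float
    n_resamples: int
    n_skipped: int
    z0: float
    acceleration: float
    distribution: np.ndarray = field(repr=False)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.point, self.lower, self.upper)


@dataclass(frozen=True)
class ReliabilityReport:
    alpha: float
    alpha_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    icc_p: float
    dice: dict[str, float]
    n_units_alpha: int
    n_units_icc: int


# ---------------------------------------------------------------------------
# Krippendorff's alpha (ordinal metric, missing data allowed)
# ---------------------------------------------------------------------------

def _as_matrix(matrix) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("rating matrix must be 2-D (units x raters)")
    return arr


def krippendorff_alpha(
    matrix,
    level: str = "ordinal",
    na_codes: Sequence[float] = NA_CODES,
) -> float:
    """Krippendorff's alpha over a units x raters matrix.

    NaN cells and ``na_codes`` values count as missing; units with fewer
    than two non-missing ratings drop out of the coincidence matrix but do
    not invalidate the computation.
    """
    if level not in ("ordinal", "nominal"):
        raise ValueError(f"unsupported level {level!r}")
    arr = _as_matrix(matrix).copy()
    for code in na_codes:
        arr[arr == code] = np.nan

    values = np.unique(arr[~np.isnan(arr)])
    if values.size == 0:
        raise DegenerateStatisticError("all ratings missing")
    vindex = {v: i
              for i, v in enumerate(values)}
    k = values.size

    # Coincidence matrix: each orderable pair within a unit contributes
    # 1/(m_u - 1) to both (c, k) and (k, c).
    coincidence = np.zeros((k, k))
    for unit in arr:
        obs = unit[~np.isnan(unit)]
        m = obs.size
        if m < 2:
            continue
        for i in range(m):
            for j in range(m):
                if i != j:
                    coincidence[vindex[obs[i]], vindex[obs[j]]] += 1.0 / (m - 1)

    n_c = coincidence.sum(axis=1)
    n_total = n_c.sum()
    if n_total <= 1:
        raise DegenerateStatisticError("no unit has two or more ratings")

    if level == "ordinal":
        # delta^2(c, d) = (sum of margins from c to d, minus half the two
        # endpoint margins)^2 -- the cumulative-margin ordinal metric.
        delta2 = np.zeros((k, k))
        for c in range(k):
            for d in range(k):
                lo, hi = min(c, d), max(c, d)
                s = n_c[lo : hi + 1].sum() - (n_c[c] + n_c[d]) / 2.0
                delta2[c, d] = s * s
    else:
        delta2 = 1.0 - np.eye(k)

    d_observed = (coincidence * delta2).sum()
    expected = np.outer(n_c, n_c) * delta2
    d_expected = expected.sum() / (n_total - 1)
    if d_expected == 0:
        # only one distinct value coincides; agreement is perfect by fiat
        return 1.0
    return 1.0 - d_observed / d_expected


# ---------------------------------------------------------------------------
# ICC(2,k): two-way random effects, average measures
# ---------------------------------------------------------------------------

def icc_2k(
    matrix,
    na_codes: Sequence[float] = NA_CODES,
) -> tuple[float, float]:
    """ICC(2,k) and its F-test p-value for a units x raters matrix.

    Units with any missing or N/A-coded cell are dropped listwise.  The
    coefficient comes from the two-way ANOVA mean squares: rows (units),
    columns (raters) and residual.
    """
    arr = _as_matrix(matrix).copy()
    for code in na_codes:
        arr[arr == code] = np.nan
    complete = arr[~np.isnan(arr).any(axis=1)]
    n, k = complete.shape
    if n < 3:
        raise InsufficientDataError(
            f"ICC(2,k) needs >= 3 complete units, got {n}"
        )
    grand = complete.mean()
    row_means = complete.mean(axis=1)
    col_means = complete.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((complete - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ms_rows == 0 and ms_err == 0:
        raise DegenerateStatisticError(
            "no between-unit variance: ICC undefined on constant ratings"
        )
    denom = ms_rows + (ms_cols - ms_err) / n
    if denom == 0:
        raise DegenerateStatisticError("degenerate variance decomposition")
    icc = (ms_rows - ms_err) / denom

    if ms_err == 0:
        p = 0.0  # perfect within-unit agreement: F is unbounded
    else:
        f = ms_rows / ms_err
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


# ---------------------------------------------------------------------------
# Dice per category, Spearman
# ---------------------------------------------------------------------------

def dice_per_category(r1: Sequence, r2: Sequence) -> dict:
    """Per-category Dice overlap between two equal-length rating vectors.

    dice(c) = 2 |both = c| / (|r1 = c| + |r2 = c|); categories absent from
    both raters are omitted.
    """
    a = list(r1)
    b = list(r2)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    cats = sorted(set(a) | set(b), key=repr)
    out = {}
    for c in cats:
        n1 = sum(x == c for x in a)
        n2 = sum(x == c for x in b)
        both = sum(x == c and y == c for x, y in zip(a, b))
        if n1 + n2 == 0:
            continue
        out[c] = 2.0 * both / (n1 + n2)
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise InsufficientDataError("Spearman needs n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateStatisticError("constant vector: correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def _bca_interval(
    distribution: np.ndarray,
    z0: float,
    acceleration: float,
    conf_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile endpoints adjusted by bias correction and acceleration.

    With z0 = acceleration = 0 this is exactly the percentile interval.
    """
    alpha = 1.0 - conf_level
    lo_hi = []
    for a in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = sps.norm.ppf(a)
        adj = z0 + (z0 + z) / (1.0 - acceleration * (z0 + z))
        lo_hi.append(float(np.quantile(distribution, sps.norm.cdf(adj))))
    return lo_hi[0], lo_hi[1]


def bootstrap_ci_bca(
    statistic: Callable,
    sample,
    n_resamples: int = 500,
    seed: Optional[int] = None,
    conf_level: float = 0.95,
) -> BootstrapResult:
    """BCa bootstrap interval for ``statistic`` over ``sample``.

    ``sample`` is an indexable of observations (rows resample jointly for a
    2-D array).  Resamples on which the statistic raises or returns
    non-finite are skipped and counted; more than 50% skipped is an error.
    Deterministic for a fixed seed.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    sample = np.asarray(sample)
    n = sample.shape[0]
    if n < 2:
        raise InsufficientDataError("bootstrap needs >= 2 observations")
    point = float(statistic(sample))
    rng = np.random.default_rng(seed)

    boot = []
    skipped = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            value = float(statistic(sample[idx]))
        except Exception:
            skipped += 1
            continue
        if not np.isfinite(value):
            skipped += 1
            continue
        boot.append(value)
    if skipped > n_resamples / 2:
        raise DegenerateStatisticError(
            f"statistic undefined on {skipped}/{n_resamples} resamples"
        )
    boot = np.asarray(boot)

    if np.all(boot == point):
        return BootstrapResult(
            point, point, point, n_resamples, skipped, 0.0, 0.0, boot
        )

    # Bias correction from the bootstrap distribution's position around the
    # point estimate (midrank handling of exact ties).
    prop = (np.sum(boot < point) + 0.5 * np.sum(boot == point)) / boot.size
    prop = min(max(prop, 1.0 / (2 * boot.size)), 1.0 - 1.0 / (2 * boot.size))
    z0 = float(sps.norm.ppf(prop))

    # Acceleration from jackknife influence values.
    jack = []
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        try:
            jack.append(float(statistic(sample[idx])))
        except Exception:
            continue
    jack = np.asarray(jack)
    if jack.size >= 2:
        dev = jack.mean() - jack
        denom = (dev**2).sum() ** 1.5
        accel = float((dev**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    else:
        accel = 0.0

    lower, upper = _bca_interval(boot, z0, accel, conf_level)
    return BootstrapResult(
        point, lower, upper, n_resamples, skipped, z0, accel, boot
    )


# ---------------------------------------------------------------------------
# Responder rate tables
# ---------------------------------------------------------------------------

NOTE_CATEGORY_LABELS = {
    0.0: "na",
    0.5: "intolerance",
    1.0: "improved",
    2.0: "no_change",
    3.0: "worsen",
}
NOTE_CATEGORY_ORDER = ("na", "intolerance", "improved", "no_change", "worsen")
RESPONDER_ORDER = ("responder", "non_responder", "intolerant", "not_evaluable")


def _counts_and_pct(series: pd.Series, order: Sequence[str]) -> pd.DataFrame:
    counts = series.value_counts().reindex(order, fill_value=0)
    total = int(counts.sum())
    pct = counts / total * 100.0 if total else counts * 0.0
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "percent": [round_half_up(p, 1) for p in pct],
        }
    )


def responder_rate_table(
    classifications: Sequence,
    scores: Sequence,
    covariates: Optional[pd.DataFrame] = None,
) -> dict[str, dict]:
    """Counts and percentages per drug class over score and responder
    categories, optionally stratified by diagnosis group and sex plus an
    age mean (SD) row.

    ``classifications`` are ResponderClassification objects for included
    episodes; ``scores`` the matching prioritized-domain EpisodeScore
    objects; ``covariates`` an optional frame indexed by episode_id with
    columns among {diagnosis_group, sex, age}.
    """
    cls_df = pd.DataFrame(
        {
            "episode_id": [c.episode_id for c in classifications],
            "drug_class": [c.drug_class for c in classifications],
            "responder": [c.category for c in classifications],
        }
    )
    score_df = pd.DataFrame(
        {
            "episode_id": [s.episode_id for s in scores],
            "note_category": [NOTE_CATEGORY_LABELS[s.note_value] for s in scores],
        }
    )
    df = cls_df.merge(score_df, on="episode_id", how="left")
    if covariates is not None:
        df = df.merge(
            covariates, left_on="episode_id", right_index=True, how="left"
        )

    out: dict[str, dict] = {}
    for drug_class, sub in df.groupby("drug_class"):
        entry: dict = {
            "total": int(len(sub)),
            "note_categories": _counts_and_pct(
                sub["note_category"], NOTE_CATEGORY_ORDER
            ),
            "responders": _counts_and_pct(sub["responder"], RESPONDER_ORDER),
        }
        for strat in ("diagnosis_group", "sex"):
            if strat in sub.columns:
                entry[strat] = {
                    str(level): _counts_and_pct(
                        grp["note_category"], NOTE_CATEGORY_ORDER
                    )
                    for level, grp in sub.groupby(strat)
                }
        if "age" in sub.columns:
            by_cat = sub.groupby("note_category")["age"]
            entry["age"] = pd.DataFrame(
                {"mean": by_cat.mean(), "sd": by_cat.std()}
            )
            entry["age_overall"] = (
                float(sub["age"].mean()),
                float(sub["age"].std()),
            )
        out[str(drug_class)] = entry
    return out


# ---------------------------------------------------------------------------
# Baseline-category multinomial logit with type-II LRTs
# ---------------------------------------------------------------------------

def fit_multinomial_logit(
    outcome: Sequence[str],
    covariates: pd.DataFrame,
    maxiter: int = 200,
    return_details: bool = False,
):
    """Per-covariate type-II likelihood-ratio p-values for a
    baseline-category multinomial logit.

    ``outcome`` holds category labels (not_evaluable episodes must already
    be excluded); ``covariates`` columns are the predictors, categorical
    columns dummy-coded internally.  Each covariate's p-value compares the
    full model against the model with that covariate removed.
    """
    import statsmodels.api as sm

    y = pd.Series(list(outcome), name="outcome")
    if y.nunique() < 2:
        raise InsufficientDataError("need >= 2 outcome categories")
    X = covariates.reset_index(drop=True)
    y = y.reset_index(drop=True)

    def design(cols: Sequence[str]) -> pd.DataFrame:
        if not cols:
            return pd.DataFrame(index=X.index)
        return pd.get_dummies(X[list(cols)], drop_first=True, dtype=float)

    codes = pd.Categorical(y).codes

    def fit(cols: Sequence[str]):
        exog = sm.add_constant(design(cols), has_constant="add")
        model = sm.MNLogit(codes, exog)
        res = model.fit(method="newton", maxiter=maxiter, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise DegenerateStatisticError(
                "multinomial logit did not converge: "
                f"{res.mle_retvals}"
            )
        return res

    all_cols = list(X.columns)
    full = fit(all_cols)
    n_cat = y.nunique()
    pvals: dict[str, float] = {}
    for col in all_cols:
        reduced = fit([c for c in all_cols if c != col])
        lr = 2.0 * (full.llf - reduced.llf)
        df_diff = (n_cat - 1) * design([col]).shape[1]
        pvals[col] = float(sps.chi2.sf(max(lr, 0.0), df_diff))
    if return_details:
        return pvals, {"llf": float(full.llf), "params": full.params}
    return pvals
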