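"""Residency, roaming and monthly-residency metrics with cohort statistics.

Three per-animal indices summarise array use:

* ``RI`` -- days detected divided by the days the tag was expected to be
  transmitting (nominal tag life 1877 d), with the denominator shortened
  when the animal was reported captured, or when the tag outlived its
  rating (then the span to the last detection, capped at study end).
  A very conservative measure: unobservable periods count against the
  animal.
* ``RI_max`` -- days detected divided by the span from tagging to the
  last detection, the optimistic counterpart.
* ``roaming index`` -- distinct receivers visited / receivers in the
  array (18), measuring array-wide spread rather than persistence.

Monthly RI (days detected in a month / days in the month) supports
trend analyses.  Group comparisons use Mann-Whitney and Kruskal-Wallis
rank tests with a Dunn-type post hoc, and ordinary Gaussian-error linear
models relate the indices to sex and total length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .io import DetectionSet, detection_days

__all__ = [
    "StudyConfig",
    "ModelFit",
    "compute_residency_index",
    "compute_max_residency_index",
    "compute_roaming_index",
    "compute_monthly_series",
    "build_residency_table",
    "summarize_cohort",
    "fit_linear_model",
    "select_linear_model",
    "check_overdispersion",
    "mann_whitney_u",
    "kruskal_wallis",
    "posthoc_kw",
]

TAG_LIFE_DAYS = 1877


@dataclass(frozen=True)
class StudyConfig:
    """Fixed facts of the monitoring programme used as metric denominators."""

    tag_life_days: int = TAG_LIFE_DAYS
    study_start: pd.Timestamp = pd.Timestamp("2007-04-23")
    study_end: pd.Timestamp = pd.Timestamp("2014-05-09")
    n_stations: int = 18
    #: monthly averages are summarised only through this date because most
    #: tags expired before the array was recovered
    monthly_summary_end: pd.Timestamp = pd.Timestamp("2012-12-31")

    def __post_init__(self):
        if self.tag_life_days <= 0:
            raise ValueError("tag_life_days must be positive")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")


def _as_ts(d) -> pd.Timestamp:
    return pd.Timestamp(d).tz_localize(None) if pd.Timestamp(d).tzinfo else pd.Timestamp(d)


def compute_residency_index(
    days_detected: int,
    date_tagged,
    last_detection_date,
    study_end,
    capture_date=None,
    tag_life: int = TAG_LIFE_DAYS,
) -> float:
    """Tag-life residency index: days detected over expected active days.

    The denominator is the nominal tag life, except that (a) an animal
    reported captured is only "expected" through its capture date, and
    (b) a tag detected beyond its rated life is credited the span from
    tagging to the last detection or the study end, whichever came first.
    Clamped to [0, 1].
    """
    if days_detected < 0:
        raise ValueError("days_detected must be >= 0")
    tagged = _as_ts(date_tagged)
    last = _as_ts(last_detection_date)
    end = _as_ts(study_end)
    if capture_date is not None and not pd.isna(capture_date):
        denom = (_as_ts(capture_date) - tagged).days
    elif (last - tagged).days > tag_life:
        denom = (min(last, end) - tagged).days
    else:
        denom = tag_life
    if denom <= 0:
        raise ValueError(f"non-positive expected-days denominator ({denom})")
    return float(min(max(days_detected / denom, 0.0), 1.0))


def compute_max_residency_index(
    days_detected: int, date_tagged, last_detection_date
) -> float:
    """Detection-span residency index: days detected / span to last detection.

    The span is counted inclusively ((last - tagged) in days, + 1), so an
    animal detected every day of its span scores 1.  A single-day animal
    (zero-length span with detections) scores 1.
    """
    tagged = _as_ts(date_tagged)
    last = _as_ts(last_detection_date)
    if last < tagged:
        raise ValueError("last detection precedes tagging")
    span = (last - tagged).days + 1
    if span <= 0:
        return 1.0 if days_detected > 0 else 0.0
    return float(min(days_detected / span, 1.0))


def compute_roaming_index(receivers_visited: int, n_stations: int = 18) -> float:
    """Fraction of the array's receivers the animal was ever detected at."""
    if not 0 < receivers_visited <= n_stations:
        raise ValueError(
            f"receivers_visited must be in 1..{n_stations}, got {receivers_visited}"
        )
    return receivers_visited / n_stations


def compute_monthly_series(
    ds: DetectionSet,
    shark_id: str,
    cfg: StudyConfig | None = None,
    date_tagged=None,
    min_detections_per_day: int = 2,
) -> pd.Series:
    """Monthly residency: detection days in month / days in the month.

    Indexed by calendar month (PeriodIndex) from the tagging month to the
    earlier of tag death and the monthly summary end; months without
    detections are zero.
    """
    cfg = cfg or StudyConfig()
    ev = ds.events_for(shark_id)
    if date_tagged is None:
        row = ds.sharks[ds.sharks["shark_id"].astype(str) == str(shark_id)]
        if not len(row):
            raise KeyError(f"unknown shark {shark_id!r}")
        date_tagged = row["date_tagged"].iloc[0]
    tagged = _as_ts(date_tagged)
    tag_death = tagged + pd.Timedelta(days=cfg.tag_life_days)
    end = min(tag_death, _as_ts(cfg.monthly_summary_end))
    months = pd.period_range(tagged.to_period("M"), end.to_period("M"), freq="M")
    out = pd.Series(0.0, index=months, name="monthly_ri")
    if len(ev):
        day = ev["timestamp"].dt.floor("D").dt.tz_localize(None)
        per_day = ev.assign(_day=day).groupby("_day").size()
        good_days = per_day[per_day >= min_detections_per_day].index
        month_counts = pd.Series(1, index=good_days).groupby(
            good_days.to_period("M")
        ).sum()
        for m, n in month_counts.items():
            if m in out.index:
                out[m] = n / m.days_in_month
    return out


def build_residency_table(
    ds: DetectionSet,
    cfg: StudyConfig | None = None,
    min_detections_per_day: int = 2,
) -> pd.DataFrame:
    """Per-animal summary table (one row per shark) from cleaned detections.

    Columns mirror the published per-shark table: days detected,
    receivers visited (station level), RI, RI_max and roaming index,
    joined with the tagging metadata.
    """
    cfg = cfg or StudyConfig()
    days = detection_days(ds, min_detections_per_day)
    ev = ds.events
    last = ev.groupby("transmitter_id", observed=True)["timestamp"].max().dt.tz_localize(None)
    nrec = ev.groupby("transmitter_id", observed=True)["receiver_id"].nunique()
    rows = []
    for _, sh in ds.sharks.iterrows():
        sid = str(sh["shark_id"])
        if sid not in last.index:
            continue
        d = int(days.get(sid, 0))
        rows.append(
            {
                "shark_id": sid,
                "sex": sh.get("sex"),
                "size_class": sh.get("size_class"),
                "date_tagged": sh["date_tagged"],
                "tl_cm": sh.get("tl_cm"),
                "days_detected": d,
                "receivers_visited": int(nrec[sid]),
                "ri": compute_residency_index(
                    d, sh["date_tagged"], last[sid], cfg.study_end,
                    sh.get("capture_date"), cfg.tag_life_days,
                ),
                "ri_max": compute_max_residency_index(d, sh["date_tagged"], last[sid]),
                "roaming_index": compute_roaming_index(int(nrec[sid]), cfg.n_stations),
                "last_detection": last[sid],
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(table: pd.DataFrame) -> dict:
    """Cohort statistics over a per-shark summary table.

    Returns means +/- sd of RI and RI_max, the proportion of animals with
    RI < 0.5, the count/composition of site- and array-faithful animals
    (RI_max > 0.50 and roaming < 0.50, both strict), the share of
    low-roaming (< 0.5) animals that are mature, and size-class counts.
    """
    if not len(table):
        raise ValueError("empty cohort table")
    t = table
    faithful = t[(t["ri_max"] > 0.50) & (t["roaming_index"] < 0.50)]
    low_roam = t[t["roaming_index"] < 0.50]
    out = {
        "n_sharks": int(len(t)),
        "mean_ri": float(t["ri"].mean()),
        "sd_ri": float(t["ri"].std(ddof=1)) if len(t) > 1 else 0.0,
        "mean_ri_max": float(t["ri_max"].mean()),
        "sd_ri_max": float(t["ri_max"].std(ddof=1)) if len(t) > 1 else 0.0,
        "prop_ri_lt_0.5": float((t["ri"] < 0.5).mean()),
        "n_ri_max_gt_0.5": int((t["ri_max"] > 0.5).sum()),
        "n_site_array_faithful": int(len(faithful)),
        "prop_faithful_mature_female": (
            float(((faithful["sex"] == "F") & (faithful["size_class"] == "C")).mean())
            if len(faithful)
            else float("nan")
        ),
        "prop_low_roaming_mature": (
            float((low_roam["size_class"] == "C").mean()) if len(low_roam) else float("nan")
        ),
        "prop_roaming_le_0.5": float((t["roaming_index"] <= 0.5).mean()),
        "size_class_counts": {
            cls: {
                "total": int((t["size_class"] == cls).sum()),
                "F": int(((t["size_class"] == cls) & (t["sex"] == "F")).sum()),
                "M": int(((t["size_class"] == cls) & (t["sex"] == "M")).sum()),
            }
            for cls in ("A", "B", "C")
        },
    }
    return out


@dataclass
class ModelFit:
    """A fitted linear model: term names with estimates and inference."""

    response: str
    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    family: str = "gaussian"
    aic: float = float("nan")
    n: int = 0

    def __post_init__(self):
        if not (
            len(self.terms)
            == len(self.estimates)
            == len(self.std_errors)
            == len(self.t_values)
            == len(self.p_values)
        ):
            raise ValueError("term/estimate length mismatch")

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "s.e.": self.std_errors,
                "t-value": self.t_values,
                "p-value": self.p_values,
            },
            index=self.terms,
        )


def _design(data: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    """Build a design matrix; sex enters as a male dummy (female reference)."""
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for term in predictors:
        if term == "tl":
            X["TL"] = data["tl_cm"].astype(float)
        elif term == "sex":
            X["sex"] = (data["sex"] == "M").astype(float)
        elif term == "tl:sex":
            X["TL:sex"] = data["tl_cm"].astype(float) * (data["sex"] == "M").astype(float)
        else:
            X[term] = data[term].astype(float)
    return X


def fit_linear_model(
    data: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] = ("tl",),
    family: str = "gaussian",
) -> ModelFit:
    """Gaussian-error linear model of an index on sex and/or total length.

    ``predictors`` may contain ``'tl'``, ``'sex'`` and ``'tl:sex'`` (or any
    numeric column name).  Sex is coded female = 0 (reference), male = 1.
    Complete cases only; a rank-deficient design raises, naming the
    collinear terms.
    """
    if family != "gaussian":
        raise NotImplementedError("only the Gaussian error family is fitted")
    cols = [response] + [
        c for c in ("tl_cm", "sex") if any(t in ("tl", "sex", "tl:sex") for t in predictors)
    ]
    use = data.dropna(subset=[c for c in cols if c in data.columns])
    X = _design(use, tuple(predictors))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {X.shape[1]}): terms {list(X.columns)}"
        )
    fit = sm.OLS(use[response].astype(float), X).fit()
    return ModelFit(
        response=response,
        terms=list(X.columns),
        estimates=fit.params.to_numpy(),
        std_errors=fit.bse.to_numpy(),
        t_values=fit.tvalues.to_numpy(),
        p_values=fit.pvalues.to_numpy(),
        family="gaussian",
        aic=float(fit.aic),
        n=int(fit.nobs),
    )


CANDIDATE_MODELS: tuple[tuple[str, ...], ...] = (
    (),
    ("tl",),
    ("sex",),
    ("tl", "sex"),
    ("tl", "sex", "tl:sex"),
)


def select_linear_model(
    data: pd.DataFrame, response: str
) -> tuple[ModelFit, pd.DataFrame]:
    """AIC selection among intercept, TL, sex, TL+sex and TL*sex models.

    Candidates with no residual degrees of freedom (tiny samples) are
    not considered.
    """
    candidates = [p for p in CANDIDATE_MODELS if len(data) > len(p) + 2]
    fits = [fit_linear_model(data, response, p) for p in candidates]
    table = pd.DataFrame(
        {
            "model": [" + ".join(p) if p else "1" for p in candidates],
            "aic": [f.aic for f in fits],
        }
    ).sort_values("aic", ignore_index=True)
    best = min(fits, key=lambda f: f.aic)
    return best, table


def check_overdispersion(counts, data: pd.DataFrame, predictors=("tl", "sex")) -> dict:
    """Pearson dispersion of a Poisson fit of a count response.

    A dispersion statistic well above 1 (reported threshold 1.5) flags
    that a negative-binomial error family would be more appropriate for
    count responses such as days detected.
    """
    X = _design(data, tuple(predictors))
    fit = sm.GLM(np.asarray(counts, float), X, family=sm.families.Poisson()).fit()
    dispersion = float(fit.pearson_chi2 / fit.df_resid)
    return {
        "dispersion": dispersion,
        "overdispersed": dispersion > 1.5,
        "recommended_family": "negative binomial" if dispersion > 1.5 else "poisson",
    }


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact Mann-Whitney p by enumerating group assignments.

    Handles ties; feasible for small samples (both n <= 8 enumerates at
    most C(16, 8) = 12870 assignments).
    """
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = sps.rankdata(pooled)
    stats = []
    for idx in itertools.combinations(range(n), na):
        ra = ranks[list(idx)].sum()
        u1 = ra - na * (na + 1) / 2
        u2 = na * (n - na) - u1
        stats.append(min(u1, u2))
    stats = np.asarray(stats)
    u_two = min(u_obs, na * (n - na) - u_obs)
    return float(np.mean(stats <= u_two + 1e-12))


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the tie-corrected normal approximation, switching to exact
    enumeration of all group assignments when both samples have at most
    eight observations.  Returns (U of the first sample, p).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if not len(a) or not len(b):
        raise ValueError("both samples must be non-empty")
    if len(a) <= 8 and len(b) <= 8:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = _exact_mwu_p(a, b, float(res.statistic))
        return float(res.statistic), min(p, 1.0)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with its chi-square p-value."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]) and all(
        np.ptp(g) == 0 for g in groups
    ):
        return 0.0, 1.0  # scipy raises when every value is identical
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def posthoc_kw(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons with Bonferroni correction.

    Follows a significant Kruskal-Wallis test: z-statistics from pooled
    mean ranks with tie correction, two-sided p-values multiplied by the
    number of pairs (capped at 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12 * (N - 1))
    var_base = N * (N + 1) / 12 - tie_term
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2 * sps.norm.sf(abs(z))
        p_adj = min(p_raw * n_pairs, 1.0)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["method"] = "Dunn rank sums, Bonferroni family-wise correction"
    return df
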