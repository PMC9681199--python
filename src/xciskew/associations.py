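"""Cross-sectional, intra-twin and prospective analyses of XCI skew.

Implements the cohort analyses around the categorical skew variable:

- family random-intercept linear mixed models for cross-sectional
  associations (ageing markers, blood counts, cytokines, ASCVD score),
  with per-family Bonferroni thresholds;
- myeloid-to-lymphoid ratios (MLR, NLR) from differential counts;
- twin-pair discordance summaries and the one-sided paired signed-rank
  test used in the discordant-twin design (exact enumeration null for
  small samples);
- registry-style cancer eligibility filtering, age-adjusted Cox
  proportional-hazards regression with family-clustered robust variance,
  and Kaplan-Meier summaries;
- age-band prevalence and longitudinal visit-to-visit transitions of the
  skew categories.

Model fitting is delegated to statsmodels (MixedLM) and lifelines
(CoxPHFitter, KaplanMeierFitter); this module owns the study design:
covariate schemes, filters, orientations, multiple-testing rules.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "CoxResult",
    "fit_family_mixed_model",
    "bonferroni_family",
    "derive_ratios",
    "discordant_pairs",
    "paired_wilcoxon_one_sided",
    "cancer_eligibility_filter",
    "mortality_records",
    "fit_cox",
    "kaplan_meier",
    "plot_kaplan_meier",
    "age_group_prevalence",
    "longitudinal_transitions",
    "COVARIATE_SCHEMES",
    "FAMILY_SIZES",
]

#: Fixed-effect covariate scheme per analysis family.
COVARIATE_SCHEMES = {
    "ageing": ["age"],
    "bloodcounts": ["age", "bmi", "season", "smoking_ever"],
    "ratios": ["age", "bmi", "season", "smoking_ever"],
    "cytokines": ["age", "season"],
    "ascvd": ["bmi", "monocytes"],
}

#: Number of tests per analysis family (for the Bonferroni threshold).
FAMILY_SIZES = {"ageing": 7, "bloodcounts": 10, "ratios": 2, "cytokines": 5, "ascvd": 1}

#: Bonferroni thresholds as printed (rounded) rather than recomputed, so
#: significance flags match the reported rounding exactly.
_PRINTED_THRESHOLDS = {7: 0.007, 10: 0.005, 2: 0.025, 5: 0.01, 1: 0.05}

DEFAULT_AGE_BANDS = ((-np.inf, 40.0), (40.0, 60.0), (60.0, 70.0), (70.0, np.inf))
DEFAULT_BAND_LABELS = ("<40", "40-59", "60-69", ">=70")


@dataclass
class AssocResult:
    """One fixed-effect association test."""

    outcome: str
    predictor: str
    estimate: float
    se: float
    pvalue: float
    n: int
    family: str | None = None
    bonferroni_threshold: float | None = None
    significant: bool | None = None
    method: str = "mixedlm"

    def apply_family(self, family: str) -> "AssocResult":
        self.family = family
        self.bonferroni_threshold = bonferroni_family([self.pvalue], FAMILY_SIZES[family])[0]
        self.significant = bool(self.pvalue < self.bonferroni_threshold)
        return self


@dataclass
class CoxResult:
    """Hazard ratio for the binary skew flag from a Cox regression."""

    hr: float
    ci_low: float
    ci_high: float
    pvalue: float
    log_hr: float
    se: float
    n: int
    n_events: int
    ph_test_pvalue: float
    covariates: tuple[str, ...]


# ---------------------------------------------------------------------------
# mixed models


def fit_family_mixed_model(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    fixed_covariates: list[str] | tuple[str, ...] = (),
    family_col: str = "family_id",
    standardize_outcome: bool = True,
) -> AssocResult:
    """Linear mixed model with a family random intercept.

    Fits ``outcome ~ predictor + covariates + (1 | family)`` and returns the
    predictor's fixed-effect estimate, standard error and Wald p-value.
    The outcome is z-scored by default (the reported blood-count and
    cytokine analyses work on normalised outcomes).  Relatedness and family
    structure are absorbed by the random intercept.

    A singular random-effect fit falls back to ordinary least squares with
    a logged warning.
    """
    cols = [outcome, predictor, *fixed_covariates, family_col]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns for mixed model: {missing}")
    df = table[cols].dropna().copy()
    if standardize_outcome:
        sd = df[outcome].std(ddof=1)
        if sd > 0:
            df[outcome] = (df[outcome] - df[outcome].mean()) / sd
    rhs = " + ".join([predictor, *fixed_covariates]) or "1"
    formula = f"{outcome} ~ {rhs}"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df[family_col])
            res = model.fit(reml=True)
            singular = not np.isfinite(res.bse.get(predictor, np.nan))
        except (np.linalg.LinAlgError, ValueError):
            res, singular = None, True

    method = "mixedlm"
    if res is None or singular:
        logger.warning(
            "mixed model for %s ~ %s singular or failed; falling back to OLS",
            outcome, predictor,
        )
        res = smf.ols(formula, df).fit()
        method = "ols"

    return AssocResult(
        outcome=outcome,
        predictor=predictor,
        estimate=float(res.params[predictor]),
        se=float(res.bse[predictor]),
        pvalue=float(res.pvalues[predictor]),
        n=len(df),
        method=method,
    )


def bonferroni_family(p_values, family_size: int):
    """Per-family Bonferroni threshold and significance flags.

    Thresholds for the family sizes used in the reported analyses are the
    printed rounded values (7 -> 0.007, 10 -> 0.005, 2 -> 0.025, 5 -> 0.01);
    other sizes use 0.05 / m.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    threshold = _PRINTED_THRESHOLDS.get(family_size, 0.05 / family_size)
    flags = np.asarray(p_values, dtype=float) < threshold
    return threshold, flags


# ---------------------------------------------------------------------------
# blood-count ratios


def derive_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Append monocyte- and neutrophil-to-lymphocyte ratios (MLR, NLR).

    Ratios are always computed, never accepted from the input.  Rows with
    zero (or missing) lymphocyte counts keep their ratio as missing, with a
    warning, and remain in the table.
    """
    for col in ("monocytes", "neutrophils", "lymphocytes"):
        if col not in table.columns:
            raise KeyError(f"derive_ratios requires column {col!r}")
    out = table.copy()
    lymph = out["lymphocytes"].to_numpy(dtype=float)
    bad = ~(lymph > 0)
    if bad.any():
        logger.warning("%d rows with zero/missing lymphocyte count; MLR/NLR set missing",
                       int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out["mlr"] = np.where(bad, np.nan, out["monocytes"].to_numpy(dtype=float) / lymph)
        out["nlr"] = np.where(bad, np.nan, out["neutrophils"].to_numpy(dtype=float) / lymph)
    return out


# ---------------------------------------------------------------------------
# twin-pair analyses


def discordant_pairs(
    table: pd.DataFrame,
    category_col: str = "skew_category",
    family_col: str = "family_id",
    zygosity_col: str = "zygosity",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Twin pairs whose categorical skew status differs.

    Returns ``(pairs, summary)``: one row per complete MZ/DZ pair with both
    categories and a discordance flag, and a per-zygosity summary with
    counts and the discordance proportion (percent).  Families without
    exactly two typed members are skipped with a log entry.
    """
    df = table.dropna(subset=[category_col])
    rows = []
    for (fam, zyg), grp in df.groupby([family_col, zygosity_col]):
        if zyg not in ("MZ", "DZ"):
            continue
        if len(grp) != 2:
            logger.info("family %s: %d typed member(s); pair skipped", fam, len(grp))
            continue
        a, b = grp[category_col].to_numpy()
        rows.append((fam, zyg, int(a), int(b), bool(a != b)))
    pairs = pd.DataFrame(rows, columns=[family_col, zygosity_col,
                                        "category_a", "category_b", "discordant"])
    summaries = []
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs[zygosity_col] == zyg]
        n, d = len(sub), int(sub["discordant"].sum())
        pct = 100.0 * d / n if n else np.nan
        summaries.append((zyg, n, d, pct))
    summary = pd.DataFrame(summaries, columns=["zygosity", "n_pairs",
                                               "n_discordant", "pct_discordant"])
    return pairs, summary


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def paired_wilcoxon_one_sided(
    pair_values,
    alternative: str = "greater",
    zero_method: str = "wilcox",
    exact_max: int = 12,
) -> tuple[float, float]:
    """One-sided paired Wilcoxon signed-rank test.

    ``pair_values`` is a sequence of ``(twin_a, twin_b)`` value pairs; the
    test statistic is the sum of ranks of positive differences
    ``twin_a - twin_b`` (orientation: a = the skewed co-twin), and
    ``alternative="greater"`` tests whether twin a's values are shifted
    upward.  Zero differences are dropped before ranking (``"wilcox"``) or
    retained in the ranking and their ranks split (``"pratt"``).

    For up to ``exact_max`` informative pairs the null distribution is the
    full enumeration of all 2^n sign assignments over the observed
    (tie-averaged) ranks; beyond that a normal approximation with tie
    correction and continuity correction is used.

    Returns ``(statistic, p_value)``.
    """
    arr = np.asarray(pair_values, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        d = arr[:, 0] - arr[:, 1]
    elif arr.ndim == 1:
        d = arr
    else:
        raise ValueError("pair_values must be (n, 2) pairs or a 1-d difference array")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if alternative == "less":
        d = -d

    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            raise ValueError("all paired differences are zero; the test is undefined")
        w_obs, ranks = _signed_rank_stat(d)
    elif zero_method == "pratt":
        if np.all(d == 0):
            raise ValueError("all paired differences are zero; the test is undefined")
        ranks_all = stats.rankdata(np.abs(d))
        nonzero = d != 0
        w_obs = float(ranks_all[d > 0].sum())
        ranks = ranks_all[nonzero]
        d = d[nonzero]
    else:
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")

    n = d.size
    if n <= exact_max:
        # exact sign-flip null over the observed rank values
        total = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.dot(signs, ranks))
            if w >= w_obs - 1e-12:
                total += 1
        p = total / 2.0**n
    else:
        mu = ranks.sum() / 2.0
        var = float(np.square(ranks).sum()) / 4.0
        z = (w_obs - mu - 0.5) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    return w_obs, float(p)


# ---------------------------------------------------------------------------
# survival analyses

EXCL_NONE = "none"
EXCL_PRIOR = "prior_cancer"
EXCL_WITHIN6M = "within_6_months"


def cancer_eligibility_filter(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    study_end,
    followup_years: float = 10.0,
    exclusion_window_months: int = 6,
    nmsc_site: str = "Non-melanoma skin cancer",
) -> pd.DataFrame:
    """Apply the registry eligibility rules and build survival records.

    Rules, applied per individual:

    - non-melanoma skin cancer reports are filtered out first: they neither
      count as events nor exclude the individual;
    - any remaining diagnosis on or before study entry, or within
      ``exclusion_window_months`` of entry (boundary inclusive), excludes
      the individual;
    - otherwise the event is the first diagnosis; individuals without one
      are censored at ``min(followup_years, study end, death)``.

    ``cohort`` needs ``individual_id``, ``entry_date`` and (optionally)
    ``death_date``; ``diagnoses`` needs ``individual_id``,
    ``diagnosis_date`` and ``site_group``.  Durations are computed in days
    and converted to years by /365.25.

    Returns one row per individual: ``time_years``, ``event``, ``eligible``
    and ``exclusion_reason``.  Inconsistent dates (death before entry,
    non-positive follow-up) raise a validation error naming the ids.
    """
    study_end = pd.Timestamp(study_end)
    cohort = cohort.copy()
    cohort["entry_date"] = pd.to_datetime(cohort["entry_date"])
    death = pd.to_datetime(cohort["death_date"]) if "death_date" in cohort.columns \
        else pd.Series(pd.NaT, index=cohort.index)

    bad = cohort.loc[death.notna() & (death < cohort["entry_date"]), "individual_id"]
    if len(bad):
        raise ValueError(f"death before study entry for: {sorted(bad)}")
    bad = cohort.loc[cohort["entry_date"] > study_end, "individual_id"]
    if len(bad):
        raise ValueError(f"study entry after study end for: {sorted(bad)}")

    dx = diagnoses.copy()
    dx["diagnosis_date"] = pd.to_datetime(dx["diagnosis_date"])
    dx = dx[dx["site_group"] != nmsc_site]  # filtered reports; individual stays at risk
    unknown = set(dx["individual_id"]) - set(cohort["individual_id"])
    if unknown:
        raise ValueError(f"diagnoses for ids absent from the cohort: {sorted(unknown)}")
    first_dx = dx.groupby("individual_id")["diagnosis_date"].min()

    rows = []
    for row in cohort.itertuples():
        entry = row.entry_date
        d_date = first_dx.get(row.individual_id, pd.NaT)
        death_date = death.loc[row.Index]
        cutoff = entry + pd.DateOffset(months=exclusion_window_months)
        if pd.notna(d_date) and d_date <= cutoff:
            reason = EXCL_PRIOR if d_date <= entry else EXCL_WITHIN6M
            rows.append((row.individual_id, np.nan, 0, False, reason))
            continue
        censor_date = min(study_end, entry + pd.Timedelta(days=followup_years * 365.25))
        if pd.notna(death_date):
            censor_date = min(censor_date, death_date)
        if pd.notna(d_date) and d_date <= censor_date:
            time = (d_date - entry).days / 365.25
            event = 1
        else:
            time = (censor_date - entry).days / 365.25
            event = 0
        if time < 0:
            raise ValueError(f"negative follow-up time for {row.individual_id}")
        time = max(time, 0.5 / 365.25)  # same-day death/censoring: half a day at risk
        rows.append((row.individual_id, time, event, True, EXCL_NONE))
    return pd.DataFrame(rows, columns=["individual_id", "time_years", "event",
                                       "eligible", "exclusion_reason"])


def mortality_records(
    cohort: pd.DataFrame,
    study_end,
    followup_years: float = 10.0,
) -> pd.DataFrame:
    """Survival records for all-cause mortality.

    Mirrors the cancer analysis minus the diagnosis-based exclusions:
    everyone is eligible, the event is death, and censoring is at
    ``min(followup_years, study end)``.
    """
    study_end = pd.Timestamp(study_end)
    entry = pd.to_datetime(cohort["entry_date"])
    death = pd.to_datetime(cohort["death_date"]) if "death_date" in cohort.columns \
        else pd.Series(pd.NaT, index=cohort.index)
    cap = entry + pd.Timedelta(days=followup_years * 365.25)
    censor = cap.where(cap <= study_end, study_end)
    event = death.notna() & (death <= censor)
    end = death.where(event, censor)
    time = (end - entry).dt.days / 365.25
    return pd.DataFrame({
        "individual_id": cohort["individual_id"],
        "time_years": time,
        "event": event.astype(int),
        "eligible": True,
        "exclusion_reason": EXCL_NONE,
    })


def fit_cox(
    records: pd.DataFrame,
    cohort: pd.DataFrame,
    skew_col: str = "skew_binary",
    adjust_zygosity: bool = True,
    family_col: str = "family_id",
) -> CoxResult:
    """Age-adjusted Cox regression of the binary skew flag.

    Fits a proportional-hazards model for the eligible records with age
    (and optionally zygosity) as covariates.  Relatedness is handled with
    family-clustered robust (sandwich) standard errors.  A Schoenfeld-type
    proportional-hazards test is run and its minimum p-value reported.
    """
    df = records[records["eligible"]].merge(
        cohort[["individual_id", skew_col, "age", "zygosity", family_col]],
        on="individual_id",
    )
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events among eligible records; Cox model is undefined")

    covs = [skew_col, "age"]
    fit_df = df[["time_years", "event", skew_col, "age", family_col]].copy()
    if adjust_zygosity:
        dummies = pd.get_dummies(df["zygosity"], prefix="zyg", drop_first=True, dtype=float)
        # drop covariates with no variation (e.g. single-zygosity fixtures)
        dummies = dummies.loc[:, dummies.std() > 0]
        fit_df = pd.concat([fit_df, dummies], axis=1)
        covs += list(dummies.columns)

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            fit_df,
            duration_col="time_years",
            event_col="event",
            cluster_col=family_col,
            robust=True,
        )
        try:
            ph = proportional_hazard_test(cph, fit_df, time_transform="rank")
            ph_p = float(ph.summary["p"].min())
        except Exception:  # degenerate fixtures can break the diagnostic
            ph_p = np.nan

    coef = float(cph.params_[skew_col])
    se = float(cph.standard_errors_[skew_col])
    ci = cph.confidence_intervals_
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(ci.loc[skew_col].iloc[0])),
        ci_high=float(np.exp(ci.loc[skew_col].iloc[1])),
        pvalue=float(cph.summary.loc[skew_col, "p"]),
        log_hr=coef,
        se=se,
        n=len(df),
        n_events=n_events,
        ph_test_pvalue=ph_p,
        covariates=tuple(covs),
    )


def kaplan_meier(
    records: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    group_col: str = "skew_binary",
) -> dict:
    """Product-limit survival curves and cumulative events per skew group.

    Returns a dict mapping group label to a dict with the fitted
    ``KaplanMeierFitter``, the step-function ``survival`` DataFrame, group
    size ``n``, event count ``n_events`` and the cumulative event
    percentage ``pct_events``.
    """
    df = records[records["eligible"]].copy()
    if group_col not in df.columns:
        if cohort is None:
            raise KeyError(f"{group_col} not in records and no cohort table given")
        df = df.merge(cohort[["individual_id", group_col]], on="individual_id")
    out = {}
    for grp, sub in df.groupby(group_col):
        kmf = KaplanMeierFitter(label=str(grp))
        kmf.fit(sub["time_years"], sub["event"])
        n, n_events = len(sub), int(sub["event"].sum())
        out[grp] = {
            "model": kmf,
            "survival": kmf.survival_function_,
            "n": n,
            "n_events": n_events,
            "pct_events": 100.0 * n_events / n,
        }
    return out


def plot_kaplan_meier(km: dict, path=None, labels=("random XCI", "XCI-skew")):
    """Plot the per-group survival curves and cumulative events.

    Top panel: Kaplan-Meier survival; bottom panel: cumulative observed
    events.  Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 7), sharex=True,
                                   height_ratios=[2, 1])
    for (grp, info), label in zip(sorted(km.items()), labels):
        info["model"].plot_survival_function(ax=ax1, label=f"{label} (n={info['n']})")
        ev = info["model"].event_table
        ax2.step(ev.index, ev["observed"].cumsum(), where="post", label=label)
    ax1.set_ylabel("Survival (cancer-free)")
    ax2.set_ylabel("Cumulative events")
    ax2.set_xlabel("Years since DNA sampling")
    ax2.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


# ---------------------------------------------------------------------------
# descriptive summaries


def age_group_prevalence(
    table: pd.DataFrame,
    age_col: str = "age",
    category_col: str = "skew_category",
    bands=DEFAULT_AGE_BANDS,
    labels=DEFAULT_BAND_LABELS,
) -> pd.DataFrame:
    """Per-age-band counts and prevalence of the skew categories.

    Default bands are <40, 40-59, 60-69 and >=70 years.  ``pct_skewed`` is
    the prevalence of any skew (category >= 1, i.e. folded XCI >= the 1-SD
    cut) and ``pct_extreme`` of category 2; empty bands report NaN.
    Percentages are rounded to the integer precision used in reporting.
    """
    df = table.dropna(subset=[age_col, category_col])
    edges = [b[0] for b in bands] + [bands[-1][1]]
    band = pd.cut(df[age_col], bins=edges, right=False, labels=labels)
    rows = []
    for lab in labels:
        sub = df[band == lab]
        n = len(sub)
        counts = [int((sub[category_col] == k).sum()) for k in (0, 1, 2)]
        n_skewed = counts[1] + counts[2]
        rows.append({
            "age_band": lab,
            "n": n,
            "n_random": counts[0],
            "n_skewed": counts[1],
            "n_extreme": counts[2],
            "pct_skewed": round(100.0 * n_skewed / n) if n else np.nan,
            "pct_extreme": round(100.0 * counts[2] / n) if n else np.nan,
        })
    return pd.DataFrame(rows)


def longitudinal_transitions(
    visit1: pd.Series,
    visit2: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Visit-1 to visit-2 transition counts and row percentages.

    Both inputs are skew categories indexed by individual id; unmatched ids
    are dropped with a log entry.  Returns ``(counts, row_pct)`` as 3x3
    DataFrames indexed by visit-1 category, with percentages rounded to one
    decimal.
    """
    common = visit1.index.intersection(visit2.index)
    dropped = len(visit1.index.union(visit2.index)) - len(common)
    if dropped:
        logger.info("%d unmatched individual(s) dropped from transition table", dropped)
    v1 = visit1.loc[common].astype(int)
    v2 = visit2.loc[common].astype(int)
    cats = [0, 1, 2]
    counts = pd.crosstab(v1, v2).reindex(index=cats, columns=cats, fill_value=0)
    counts.index.name, counts.columns.name = "visit1", "visit2"
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (100.0 * counts.div(totals, axis=0)).round(1)
    return counts, pct
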