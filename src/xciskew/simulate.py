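"""Synthetic twin-cohort and assay generator.

Generates data with the statistical structure the downstream analyses
assume, at three layers:

1. *Truth*: each individual carries a latent inactive-cell fraction
   ``p`` in [0, 1].  The folded skew ``max(p, 1-p)`` is drawn from a Beta
   distribution rescaled to [0.5, 1] whose location increases linearly
   with age past 40 (age-acquired skew); co-twins share a Gaussian-copula
   latent value with zygosity-specific correlation (MZ > DZ), and twins in
   a pair share their age.
2. *Assay*: triplicate mock/HpaII peak pairs plus a single MspI control
   per sample.  Mock heights are a base amplitude times a length-dependent
   amplification bias (shorter allele favoured) times multiplicative
   lognormal noise; HpaII heights are additionally scaled by the inactive
   fraction of each allele, so the normalised ratio Rn = Rh/Rm recovers
   p/(1-p) exactly when noise is off.  Configurable fractions of samples
   are planted as homozygous (uninformative), failed, or replicate-CV
   failures, assigned as exact disjoint counts so sample accounting is
   reproducible.
3. *Phenotypes and events*: blood counts, cytokines and an ASCVD risk
   score from linear models with a family random intercept and planted
   standardized skew effects; cancer/death event times exponential under
   proportional hazards with configurable log-hazard ratios, staggered
   study entry and administrative censoring.

All randomness flows from ``SimConfig.seed`` through one
``numpy.random.Generator``; identical configs give identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .humara import PeakPair, SampleAssay

__all__ = ["SimConfig", "simulate_truth", "simulate_assay", "simulate_assays",
           "simulate_phenotypes", "simulate_events", "simulate_all",
           "expected_cancer_events"]

_STUDY_END = pd.Timestamp("2020-01-01")

#: Cancer site groups used for synthetic diagnoses.  Non-melanoma skin
#: cancer is special-cased by the eligibility filter (filtered, not an event).
SITE_GROUPS = (
    "Breast",
    "Haematopoietic/Lymphoid Tissue",
    "Lung",
    "Colorectal",
    "Other",
)
NMSC_SITE = "Non-melanoma skin cancer"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Structural defaults mirror the study this package was designed around:
    423 MZ pairs, 257 DZ pairs and 215 singletons (1575 individuals), ages
    19-99, with assay attrition fractions matching 194 failed, 601
    homozygous and 12 CV-excluded out of 2382 assayed.  Effect sizes with
    no published magnitude (monocyte, IL-10, ASCVD) are free parameters.
    """

    seed: int = 0
    # cohort structure
    n_mz_pairs: int = 423
    n_dz_pairs: int = 257
    n_singletons: int = 215
    age_range: tuple[float, float] = (19.0, 99.0)
    # latent skew model (Beta on [0.5, 1])
    base_location: float = 0.28      # raw-Beta mean below age 40
    skew_drift_rate: float = 0.044   # location increase per decade past 40
    concentration: float = 3.0       # Beta concentration (a + b)
    mz_concordance: float = 0.68     # copula correlation, MZ pairs
    dz_concordance: float = 0.05     # copula correlation, DZ pairs
    # assay layer
    assay_noise_sd: float = 0.05      # lognormal sigma on peak heights
    amplification_bias: float = 1.2   # shorter-allele amplification factor
    base_amplitude: float = 2000.0    # RFU
    stutter_fraction: float = 0.0     # height fraction shed into -3bp stutter
    homozygous_fraction: float = 601 / 2382
    fail_fraction: float = 194 / 2382
    cv_fail_fraction: float = 12 / 2382
    # phenotype layer (standardized effects of binary skew)
    family_sd: float = 0.3            # family random-intercept SD
    monocyte_effect: float = 0.2
    il10_effect: float = -0.45
    ascvd_effect: float = 0.3
    # event layer
    cancer_log_hr: float = math.log(1.95)
    mortality_log_hr: float = math.log(1.39)
    age_log_hr_per_year: float = 0.05
    baseline_hazard: float = 2.7e-3   # cancer events / person-year at age 60
    mortality_baseline_hazard: float = 1.8e-3
    followup_years: float = 10.0
    prior_cancer_fraction: float = 0.0
    nmsc_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("homozygous_fraction", "fail_fraction", "cv_fail_fraction",
                     "stutter_fraction", "prior_cancer_fraction", "nmsc_fraction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        for name in ("mz_concordance", "dz_concordance"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.concentration <= 0 or self.base_amplitude <= 0:
            raise ValueError("concentration and base_amplitude must be positive")

    @property
    def n_individuals(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_singletons

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# layer 1: latent truth


def _beta_params(config: SimConfig, age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Age-dependent Beta(a, b) parameters of the raw folded-skew variable."""
    decades_past_40 = np.clip(age - 40.0, 0.0, None) / 10.0
    t = config.base_location + config.skew_drift_rate * decades_past_40
    t = np.clip(t, 1e-3, 0.95)
    a = config.concentration * t
    b = config.concentration * (1.0 - t)
    return a, b


def folded_exceedance(config: SimConfig, age: float, folded_cut: float) -> float:
    """Closed-form P(folded skew >= folded_cut) at a given age.

    The folded skew is 0.5 + 0.5 * X with X ~ Beta(a(age), b(age)), so the
    band prevalence the generator implies is available analytically and can
    serve as the oracle for Monte-Carlo checks.
    """
    a, b = _beta_params(config, np.asarray([age], dtype=float))
    x = 2.0 * (folded_cut - 0.5)
    return float(stats.beta.sf(x, a[0], b[0]))


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the latent per-individual truth table.

    Returns a DataFrame with columns ``individual_id``, ``family_id``,
    ``zygosity`` (MZ/DZ/singleton), ``age``, ``p_inactive`` (inactive-cell
    fraction of allele 1, in [0, 1]) and ``folded_true`` (percent scale).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range

    rows = []
    fam = 0

    def _pair_block(n_pairs: int, zygosity: str, rho: float) -> None:
        nonlocal fam
        ages = rng.uniform(lo, hi, size=n_pairs)
        z_fam = rng.standard_normal(n_pairs)
        z_ind = rng.standard_normal((n_pairs, 2))
        z = math.sqrt(rho) * z_fam[:, None] + math.sqrt(1.0 - rho) * z_ind
        u = stats.norm.cdf(z)
        a, b = _beta_params(config, ages)
        for i in range(n_pairs):
            fam += 1
            for j in range(2):
                raw = stats.beta.ppf(u[i, j], a[i], b[i])
                rows.append((f"F{fam:05d}", zygosity, ages[i], raw))

    _pair_block(config.n_mz_pairs, "MZ", config.mz_concordance)
    _pair_block(config.n_dz_pairs, "DZ", config.dz_concordance)

    ages_s = rng.uniform(lo, hi, size=config.n_singletons)
    a, b = _beta_params(config, ages_s)
    raw_s = stats.beta.ppf(rng.uniform(size=config.n_singletons), a, b)
    for i in range(config.n_singletons):
        fam += 1
        rows.append((f"F{fam:05d}", "singleton", ages_s[i], raw_s[i]))

    df = pd.DataFrame(rows, columns=["family_id", "zygosity", "age", "raw"])
    folded = 0.5 + 0.5 * df["raw"].to_numpy()
    # random direction: which parental X is over-inactivated is uninformative
    sign = rng.integers(0, 2, size=len(df))
    p = np.where(sign == 1, folded, 1.0 - folded)
    df["p_inactive"] = p
    df["folded_true"] = 100.0 * folded
    df["individual_id"] = [f"I{i + 1:05d}" for i in range(len(df))]
    return df[["individual_id", "family_id", "zygosity", "age", "p_inactive", "folded_true"]]


# ---------------------------------------------------------------------------
# layer 2: assay peaks


def _noise(rng: np.random.Generator, sigma: float, size=None):
    """Mean-1 multiplicative lognormal noise."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_assay(
    truth_row,
    config: SimConfig,
    rng: np.random.Generator,
    status: str = "ok",
    n_replicates: int = 3,
) -> SampleAssay:
    """Simulate one sample's peak measurements.

    ``status`` plants a QC outcome: ``"ok"`` (informative, usable),
    ``"homozygous"`` (single peak), ``"fail"`` (no mock amplification) or
    ``"cv_fail"`` (replicates forced apart so the CV filter trips).

    With ``assay_noise_sd = 0`` and ``stutter_fraction = 0`` the quantified
    XCI equals ``100 * p_inactive`` exactly: the amplification bias applies
    to allele 1 in both digests and cancels through Rn.
    """
    p = float(truth_row["p_inactive"])
    A = config.base_amplitude
    bias = config.amplification_bias
    sf = config.stutter_fraction

    # allele sizes: CAG repeat lengths, 3 bp apart; >= 2 repeats separation
    # unless planted homozygous
    base_size = 265.0 + 3.0 * rng.integers(0, 8)
    if status == "homozygous":
        size1 = size2 = base_size
    else:
        size1 = base_size
        size2 = base_size + 3.0 * rng.integers(2, 7)

    if status == "cv_fail":
        # replicates forced to disagree far beyond the CV threshold
        offsets = np.array([-0.3, 0.0, 0.3])[:n_replicates]
        p_reps = np.clip(p + offsets, 0.02, 0.98)
    else:
        p_reps = np.full(n_replicates, p)

    mocks, hpaiis = [], []
    for r in range(n_replicates):
        if status == "fail":
            mocks.append(PeakPair(size1, size2, 0.0, 0.0))
            hpaiis.append(PeakPair(size1, size2, 0.0, 0.0))
            continue
        m1 = A * bias * _noise(rng, config.assay_noise_sd)
        m2 = A * _noise(rng, config.assay_noise_sd)
        pr = p_reps[r]
        h1 = A * bias * pr * _noise(rng, config.assay_noise_sd)
        h2 = A * (1.0 - pr) * _noise(rng, config.assay_noise_sd)
        if status == "homozygous":
            # single peak: all signal at one size
            m1, m2 = m1 + m2, 0.0
            h1, h2 = h1 + h2, 0.0
        elif sf > 0 and size2 - size1 == 3.0:
            # -1-repeat stutter of allele 2 stacks on allele 1
            m1, m2 = (1 - sf) * m1 + sf * m2, (1 - sf) * m2
            h1, h2 = (1 - sf) * h1 + sf * h2, (1 - sf) * h2
        mocks.append(PeakPair(size1, size2, m1, m2))
        hpaiis.append(PeakPair(size1, size2, h1, h2))

    # MspI cuts regardless of methylation: complete digestion leaves ~nothing
    residual = 0.0 if status == "fail" else float(A * 0.002 * rng.uniform())
    mspi = PeakPair(size1, size2, residual, 0.0)
    return SampleAssay(
        sample_id=str(truth_row["individual_id"]),
        mock_replicates=mocks,
        hpaii_replicates=hpaiis,
        mspi_peaks=mspi,
    )


def _attrition_statuses(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Assign planted QC statuses as exact, disjoint counts.

    Rounded counts (fraction x n) are assigned without replacement so a run
    with the default fractions reproduces the intended sample accounting
    exactly rather than in expectation.
    """
    n_fail = round(config.fail_fraction * n)
    n_homo = round(config.homozygous_fraction * n)
    n_cv = round(config.cv_fail_fraction * n)
    if n_fail + n_homo + n_cv > n:
        raise ValueError("attrition fractions exceed the cohort size")
    statuses = np.array(["ok"] * n, dtype=object)
    idx = rng.permutation(n)
    statuses[idx[:n_fail]] = "fail"
    statuses[idx[n_fail:n_fail + n_homo]] = "homozygous"
    statuses[idx[n_fail + n_homo:n_fail + n_homo + n_cv]] = "cv_fail"
    return statuses


def simulate_assays(truth: pd.DataFrame, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate peak tables for a whole cohort.

    Returns ``(peaks, statuses)``: a long-format peak table (one row per
    sample x digest x replicate) in the dialect `humara.read_peak_table`
    consumes, and the planted per-sample status assignment for tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    statuses = _attrition_statuses(config, len(truth), rng)
    rows = []
    for (_, row), status in zip(truth.iterrows(), statuses):
        assay = simulate_assay(row, config, rng, status=status)
        for digest, reps in (("mock", assay.mock_replicates), ("hpaii", assay.hpaii_replicates)):
            for r, pk in enumerate(reps, start=1):
                rows.append((assay.sample_id, digest, r, pk.allele1_size,
                             pk.allele1_height, pk.allele2_size, pk.allele2_height))
        pk = assay.mspi_peaks
        rows.append((assay.sample_id, "mspi", 1, pk.allele1_size,
                     pk.allele1_height, pk.allele2_size, pk.allele2_height))
    peaks = pd.DataFrame(rows, columns=["sample_id", "digest", "replicate",
                                        "allele1_size", "allele1_height",
                                        "allele2_size", "allele2_height"])
    status_df = pd.DataFrame({"individual_id": truth["individual_id"].to_numpy(),
                              "planted_status": statuses})
    return peaks, status_df


# ---------------------------------------------------------------------------
# layer 3: phenotypes


def simulate_phenotypes(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Attach phenotypes to the truth table.

    Each standardized outcome follows ``effect * skew + covariate terms +
    family intercept + noise`` with unit total variance around the linear
    predictor; positive-valued blood counts are exponentiated from the
    standardized latent so ratios stay positive.  Setting an effect to zero
    yields a null dataset for type-I-error studies.  ``skew`` here is the
    *true* binary skew indicator (folded >= 75%), so planted effects are
    defined at the truth layer, independent of assay noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(truth)
    df = truth.copy().reset_index(drop=True)
    skew = (df["folded_true"] >= 75.0).astype(int).to_numpy()
    df["skew_binary_true"] = skew
    age_c = (df["age"].to_numpy() - 60.0) / 10.0

    fam_codes, fam_idx = np.unique(df["family_id"].to_numpy(), return_inverse=True)
    fam_eff = config.family_sd * rng.standard_normal(len(fam_codes))
    u = fam_eff[fam_idx]

    def latent(effect: float, age_beta: float = 0.0, resid_sd: float = 1.0):
        return (effect * skew + age_beta * age_c + u
                + resid_sd * rng.standard_normal(n))

    df["bmi"] = np.clip(26.0 + 4.5 * rng.standard_normal(n) + 0.3 * age_c, 15, 55)
    df["obesity"] = (df["bmi"] >= 30).astype(int)
    df["smoking_ever"] = rng.integers(0, 2, size=n)
    df["season"] = np.sin(2 * np.pi * rng.uniform(size=n))

    # blood counts (10^9 cells/L); myeloid counts carry the planted effect
    df["monocytes"] = np.exp(np.log(0.50) + 0.30 * latent(config.monocyte_effect, 0.05))
    df["neutrophils"] = np.exp(np.log(3.8) + 0.28 * latent(0.5 * config.monocyte_effect, 0.05))
    df["lymphocytes"] = np.exp(np.log(1.9) + 0.25 * latent(0.0, -0.05))
    df["eosinophils"] = np.exp(np.log(0.15) + 0.5 * latent(0.0))
    df["basophils"] = np.exp(np.log(0.04) + 0.5 * latent(0.0))
    df["wbc"] = df[["monocytes", "neutrophils", "lymphocytes", "eosinophils", "basophils"]].sum(axis=1)
    df["rbc"] = 4.6 + 0.4 * latent(0.0)
    df["haemoglobin"] = 13.5 + 1.1 * latent(0.0)
    df["haematocrit"] = 0.41 + 0.03 * latent(0.0)
    df["platelets"] = 260 + 55 * latent(0.0)

    # cytokines / CRP on a normalized (z) scale; only IL-10 carries an effect
    df["il10"] = latent(config.il10_effect)
    df["il6"] = latent(0.0, age_beta=0.1)
    df["il1b"] = latent(0.0)
    df["tnf"] = latent(0.0, age_beta=0.1)
    df["crp"] = latent(0.0, age_beta=0.1)

    # ASCVD 10-year risk (%): strongly age-driven plus the planted skew shift
    ascvd_lin = latent(config.ascvd_effect, age_beta=0.9, resid_sd=0.6)
    df["ascvd_score"] = 100.0 / (1.0 + np.exp(-(ascvd_lin - 2.5)))

    # study entry: staggered accrual, observation closes at the study end
    entry_offset_days = rng.uniform(2.0 * 365.25, 17.0 * 365.25, size=n)
    df["entry_date"] = (_STUDY_END - pd.to_timedelta(entry_offset_days, unit="D")).normalize()
    return df


# ---------------------------------------------------------------------------
# layer 4: events


def simulate_events(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Simulate registry-style diagnosis and death records.

    Event times are exponential under proportional hazards:
    ``rate_i = baseline * exp(log_hr * skew_i + age_log_hr * (age_i - 60))``.
    Diagnoses after the study end are never recorded (administrative
    censoring); ``prior_cancer_fraction`` plants diagnoses before or within
    6 months of entry and ``nmsc_fraction`` plants non-melanoma skin cancer
    records, both to exercise the eligibility filter.

    Returns ``(diagnoses, cohort)``: a diagnosis table (individual_id,
    diagnosis_date, site_group) and a copy of the cohort table with a
    ``death_date`` column added.
    """
    if "skew_binary_true" not in cohort.columns and "skew_binary" not in cohort.columns:
        raise ValueError("cohort table needs a binary skew column before event simulation")
    skew_col = "skew_binary" if "skew_binary" in cohort.columns else "skew_binary_true"
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = len(cohort)
    skew = cohort[skew_col].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    entry = pd.to_datetime(cohort["entry_date"])

    def _draw_times(base: float, log_hr: float) -> np.ndarray:
        rate = base * np.exp(log_hr * skew + config.age_log_hr_per_year * (age - 60.0))
        return rng.exponential(1.0 / rate)

    t_cancer = _draw_times(config.baseline_hazard, config.cancer_log_hr)
    t_death = _draw_times(config.mortality_baseline_hazard, config.mortality_log_hr)

    ids = cohort["individual_id"].to_numpy()
    diag_rows = []
    death_dates = np.full(n, pd.NaT, dtype=object)
    for i in range(n):
        window = (_STUDY_END - entry.iloc[i]).days / 365.25
        if t_death[i] <= window:
            death_dates[i] = entry.iloc[i] + pd.to_timedelta(t_death[i] * 365.25, unit="D")
        horizon = min(window, t_death[i])
        if t_cancer[i] <= horizon:
            site = SITE_GROUPS[rng.integers(0, len(SITE_GROUPS))]
            diag_rows.append((ids[i],
                              entry.iloc[i] + pd.to_timedelta(t_cancer[i] * 365.25, unit="D"),
                              site))

    # planted filter-exercising records
    if config.prior_cancer_fraction > 0:
        n_prior = round(config.prior_cancer_fraction * n)
        for i in rng.choice(n, size=n_prior, replace=False):
            offset = rng.uniform(-5.0 * 365.25, 182.0)
            diag_rows.append((ids[i], entry.iloc[i] + pd.to_timedelta(offset, unit="D"),
                              SITE_GROUPS[rng.integers(0, len(SITE_GROUPS))]))
    if config.nmsc_fraction > 0:
        n_nmsc = round(config.nmsc_fraction * n)
        for i in rng.choice(n, size=n_nmsc, replace=False):
            offset = rng.uniform(200.0, 8.0 * 365.25)
            diag_rows.append((ids[i], entry.iloc[i] + pd.to_timedelta(offset, unit="D"),
                              NMSC_SITE))

    diagnoses = pd.DataFrame(diag_rows, columns=["individual_id", "diagnosis_date", "site_group"])
    diagnoses["diagnosis_date"] = pd.to_datetime(diagnoses["diagnosis_date"]).dt.normalize()
    out = cohort.copy()
    out["death_date"] = pd.to_datetime(pd.Series(death_dates)).dt.normalize().to_numpy()
    return diagnoses, out


def expected_cancer_events(cohort: pd.DataFrame, config: SimConfig,
                           skew_col: str = "skew_binary_true") -> float:
    """Closed-form expected number of cancer events before censoring.

    Independent exponential competing death and administrative censoring at
    ``min(followup, study end)`` give
    ``P(event_i) = r_i / (r_i + d_i) * (1 - exp(-(r_i + d_i) * c_i))``.
    Used to calibrate the baseline hazard to a target event count.
    """
    skew = cohort[skew_col].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    entry = pd.to_datetime(cohort["entry_date"])
    window = (_STUDY_END - entry).dt.days.to_numpy() / 365.25
    c = np.minimum(window, config.followup_years)
    r = config.baseline_hazard * np.exp(config.cancer_log_hr * skew
                                        + config.age_log_hr_per_year * (age - 60.0))
    d = config.mortality_baseline_hazard * np.exp(config.mortality_log_hr * skew
                                                  + config.age_log_hr_per_year * (age - 60.0))
    return float(np.sum(r / (r + d) * (1.0 - np.exp(-(r + d) * c))))


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_all(config: SimConfig, out_dir: str | Path | None = None):
    """Generate truth, peaks, cohort and event tables in one call.

    When ``out_dir`` is given, writes ``truth.tsv``, ``peaks.tsv``,
    ``cohort.tsv``, ``events.tsv`` and ``sim_config.yaml`` in the dialects
    the downstream stages read.
    """
    truth = simulate_truth(config)
    peaks, statuses = simulate_assays(truth, config)
    cohort = simulate_phenotypes(truth, config)
    diagnoses, cohort = simulate_events(cohort, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth.merge(statuses, on="individual_id").to_csv(out / "truth.tsv", sep="\t", index=False)
        peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
        cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
        diagnoses.to_csv(out / "events.tsv", sep="\t", index=False)
        config.to_yaml(out / "sim_config.yaml")
    return {"truth": truth, "statuses": statuses, "peaks": peaks,
            "cohort": cohort, "diagnoses": diagnoses}
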