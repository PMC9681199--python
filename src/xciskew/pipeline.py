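"""End-to-end orchestration: quantify -> classify -> associate / survive.

Ties the stages together behind a single configuration object, validates
the input tables, and writes a run manifest with full exclusion
accounting so the sample-flow diagram (assayed -> failed / homozygous /
CV-excluded -> analyzable) can be reconstructed from any run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import associations, humara
from .classify import classify as classify_values, fit_thresholds, save_thresholds

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults reproduce the reference settings: CV threshold 0.15, 50 RFU
    detection floor, folded-scale classification, 10-year follow-up and
    age bands split at 40/60/70.
    """

    peaks_path: str | None = None
    cohort_path: str | None = None
    events_path: str | None = None
    out_dir: str = "xskew_out"
    cv_threshold: float = humara.DEFAULT_CV_THRESHOLD
    detection_floor: float = humara.DEFAULT_DETECTION_FLOOR
    min_separation: float = humara.DEFAULT_MIN_SEPARATION
    max_residual_fraction: float = humara.DEFAULT_MAX_RESIDUAL_FRACTION
    classification_mode: str = "folded"
    analysis_families: tuple[str, ...] = ()
    followup_years: float = 10.0
    study_end: str = "2020-01-01"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "analysis_families" in data:
            data["analysis_families"] = tuple(data["analysis_families"])
        return cls(**data)


@dataclass
class RunManifest:
    """Per-stage accounting for one run.

    ``counts`` must reconcile: assayed = failed + homozygous + digestion
    failures + CV exclusions + analyzable.
    """

    config: dict
    counts: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def reconciled(self) -> bool:
        c = self.counts
        if "n_assayed" not in c:
            return False
        exclusions = (c.get("n_assay_fail", 0) + c.get("n_homozygous", 0)
                      + c.get("n_digestion_fail", 0) + c.get("n_cv_fail", 0))
        return c["n_assayed"] == exclusions + c.get("n_analyzable", 0)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def validate_inputs(
    peaks_path: str | Path | None = None,
    cohort_path: str | Path | None = None,
    events_path: str | Path | None = None,
) -> pd.DataFrame:
    """Validate input tables, returning a report of *all* violations.

    Checks headers, duplicated peak rows, and id cross-references (every
    event id must exist in the cohort; cohort ids without peaks are noted).
    The report has columns ``file``, ``check``, ``detail``; an empty report
    means the inputs are consistent.
    """
    violations = []

    peaks = cohort = events = None
    if peaks_path is not None:
        try:
            peaks = humara._read_delimited(peaks_path)
        except Exception as exc:
            violations.append(("peaks", "unreadable", str(exc)))
        else:
            missing = [c for c in humara._PEAK_COLUMNS if c not in peaks.columns]
            if missing:
                violations.append(("peaks", "missing_columns", str(missing)))
                peaks = None
            elif len(peaks) == 0:
                violations.append(("peaks", "empty", "no rows"))
            else:
                dup = peaks.duplicated(subset=["sample_id", "digest", "replicate"])
                for _, row in peaks[dup].iterrows():
                    violations.append(("peaks", "duplicate_row",
                                       f"{row['sample_id']}/{row['digest']}/{row['replicate']}"))
    if cohort_path is not None:
        cohort = humara._read_delimited(cohort_path)
        for col in ("individual_id", "family_id", "zygosity", "age"):
            if col not in cohort.columns:
                violations.append(("cohort", "missing_columns", col))
                cohort = None
                break
        if cohort is not None:
            dup_ids = cohort.loc[cohort["individual_id"].duplicated(), "individual_id"]
            for i in dup_ids:
                violations.append(("cohort", "duplicate_id", str(i)))
    if events_path is not None:
        events = humara._read_delimited(events_path)
        for col in ("individual_id", "diagnosis_date", "site_group"):
            if col not in events.columns:
                violations.append(("events", "missing_columns", col))
                events = None
                break

    if cohort is not None and peaks is not None and len(peaks):
        missing_peaks = set(cohort["individual_id"]) - set(peaks["sample_id"])
        for i in sorted(missing_peaks):
            violations.append(("cohort", "no_peaks_for_id", str(i)))
    if cohort is not None and events is not None:
        orphans = set(events["individual_id"]) - set(cohort["individual_id"])
        for i in sorted(orphans):
            violations.append(("events", "id_not_in_cohort", str(i)))

    return pd.DataFrame(violations, columns=["file", "check", "detail"])


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute quantify -> classify -> requested analyses.

    Writes per-stage outputs under ``config.out_dir`` (``xci.tsv``,
    ``thresholds.yaml``, ``cohort_classified.tsv``, ``assoc_results.tsv``,
    ``survival_summary.tsv``) and returns the manifest.  Idempotent given
    the same inputs and config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        version=_pkg_version("xciskew"),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    if config.peaks_path is None:
        raise ValueError("run_pipeline requires peaks_path")

    # stage 1: quantification
    assays = humara.read_peak_table(config.peaks_path)
    measures = humara.quantify_table(
        assays,
        cv_threshold=config.cv_threshold,
        detection_floor=config.detection_floor,
        min_separation=config.min_separation,
        max_residual_fraction=config.max_residual_fraction,
    )
    status_counts = measures["qc_status"].value_counts()
    manifest.counts.update({
        "n_assayed": len(measures),
        "n_assay_fail": int(status_counts.get(humara.QC_ASSAY_FAIL, 0)),
        "n_homozygous": int(status_counts.get(humara.QC_HOMOZYGOUS, 0)),
        "n_digestion_fail": int(status_counts.get(humara.QC_DIGESTION_FAIL, 0)),
        "n_cv_fail": int(status_counts.get(humara.QC_CV_FAIL, 0)),
        "n_analyzable": int(status_counts.get(humara.QC_PASS, 0)),
    })
    manifest.stages.append({"stage": "quantify", "n_in": len(measures),
                            "n_out": manifest.counts["n_analyzable"]})

    # stage 2: classification (thresholds fitted once on all QC-passing samples)
    passing = measures[measures["qc_status"] == humara.QC_PASS]
    thresholds = fit_thresholds(passing["xci_folded"], mode=config.classification_mode)
    measures = measures.copy()
    z = thresholds.zscore(measures["xci_folded"])
    measures["z_folded"] = z
    cats = pd.Series(pd.NA, index=measures.index, dtype="Int64")
    ok = measures["qc_status"] == humara.QC_PASS
    cats[ok] = classify_values(measures.loc[ok, "xci_folded"].to_numpy(), thresholds)
    measures["skew_category"] = cats
    measures["skew_binary"] = pd.array(
        [pd.NA if pd.isna(c) else int(c >= 1) for c in cats], dtype="Int64")
    humara.write_measures(measures, out / "xci.tsv")
    save_thresholds(thresholds, out / "thresholds.yaml")
    manifest.counts["cut1_xci"] = thresholds.cut1_xci
    manifest.counts["cut2_xci"] = thresholds.cut2_xci
    manifest.stages.append({"stage": "classify", "n_in": int(ok.sum()), "n_out": int(ok.sum())})

    cohort = None
    if config.cohort_path is not None:
        cohort = humara._read_delimited(config.cohort_path)
        cohort = cohort.merge(
            measures[["sample_id", "xci_folded", "z_folded", "skew_category", "skew_binary"]],
            left_on="individual_id", right_on="sample_id", how="left",
        ).drop(columns=["sample_id"])
        cohort = cohort[cohort["skew_category"].notna()].copy()
        if {"monocytes", "neutrophils", "lymphocytes"} <= set(cohort.columns):
            cohort = associations.derive_ratios(cohort)
        cohort.to_csv(out / "cohort_classified.tsv", sep="\t", index=False)
        manifest.stages.append({"stage": "cohort_merge",
                                "n_in": manifest.counts["n_analyzable"],
                                "n_out": len(cohort)})

    # stage 3a: association families
    if config.analysis_families and cohort is not None:
        results = []
        outcomes = {
            "ageing": [("xci_folded", "age"), ("xci_folded", "obesity"),
                   ("xci_folded", "smoking_ever")],
            "bloodcounts": [(c, "skew_category") for c in
                            ("wbc", "rbc", "haemoglobin", "haematocrit", "platelets",
                             "monocytes", "neutrophils", "lymphocytes", "eosinophils",
                             "basophils")],
            "ratios": [("mlr", "skew_category"), ("nlr", "skew_category")],
            "cytokines": [(c, "skew_category") for c in ("il10", "il6", "il1b", "tnf", "crp")],
            "ascvd": [("ascvd_score", "skew_category")],
        }
        for fam in config.analysis_families:
            covs = associations.COVARIATE_SCHEMES[fam]
            for outcome, predictor in outcomes[fam]:
                if outcome not in cohort.columns:
                    logger.warning("outcome %s absent; skipped", outcome)
                    continue
                covs_used = [c for c in covs if c != predictor and c != outcome]
                res = associations.fit_family_mixed_model(
                    cohort, outcome, predictor, covs_used,
                ).apply_family(fam)
                results.append(asdict(res))
        if results:
            pd.DataFrame(results).to_csv(out / "assoc_results.tsv", sep="\t", index=False)
            manifest.stages.append({"stage": "associate", "n_in": len(cohort),
                                    "n_out": len(results)})

    # stage 3b: survival
    if config.events_path is not None and cohort is not None:
        diagnoses = humara._read_delimited(config.events_path)
        # registry reports for samples that failed QC carry no skew measure
        diagnoses = diagnoses[diagnoses["individual_id"].isin(cohort["individual_id"])]
        records = associations.cancer_eligibility_filter(
            cohort, diagnoses, study_end=config.study_end,
            followup_years=config.followup_years,
        )
        cox = associations.fit_cox(records, cohort)
        km = associations.kaplan_meier(records, cohort)
        summary = pd.DataFrame([{
            "analysis": "cancer",
            "n_eligible": int(records["eligible"].sum()),
            "n_excluded": int((~records["eligible"]).sum()),
            "n_events": cox.n_events,
            "hr": cox.hr, "ci_low": cox.ci_low, "ci_high": cox.ci_high,
            "pvalue": cox.pvalue, "ph_test_pvalue": cox.ph_test_pvalue,
            **{f"pct_events_group{g}": info["pct_events"] for g, info in km.items()},
        }])
        summary.to_csv(out / "survival_summary.tsv", sep="\t", index=False)
        associations.plot_kaplan_meier(km, out / "kaplan_meier.png")
        manifest.stages.append({"stage": "survival", "n_in": len(records),
                                "n_out": int(records["eligible"].sum())})

    if not manifest.reconciled():
        raise RuntimeError("manifest counts do not reconcile; pipeline aborted")
    manifest.write(out / "manifest.json")
    return manifest
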