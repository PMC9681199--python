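"""Quantification of X-chromosome inactivation (XCI) from HUMARA peak data.

The human androgen receptor assay (HUMARA) measures XCI skew in 46,XX
samples by combining a methylation-sensitive restriction digest with PCR
across the polymorphic (CAG)n repeat in the first exon of *AR*.  The
inactive X is methylated at the HpaII sites flanking the repeat, so after
an HpaII digest only inactive-X alleles remain amplifiable; a mock digest
amplifies both alleles and provides the per-allele amplification baseline.
For each replicate the allele-1/allele-2 peak-height ratio of the HpaII
digest (Rh) is normalised by the mock-digest ratio (Rm):

    Rn  = Rh / Rm
    XCI% = 100 * Rn / (Rn + 1)

so 50% is balanced inactivation and 0%/100% are complete skew in either
direction.  Because the direction (maternal vs paternal) is uninformative,
XCI% is folded onto [50, 100] for analysis.

This module turns per-sample peak tables (triplicate mock + HpaII digests,
single MspI digestion-efficiency control) into quality-controlled XCI
measurements, applying the replicate coefficient-of-variation filter,
heterozygosity (informativeness) check and digestion control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakPair",
    "SampleAssay",
    "XCIMeasure",
    "AssayFailure",
    "DigestionFailure",
    "replicate_xci",
    "fold_xci",
    "is_informative",
    "digestion_control_ok",
    "quantify_sample",
    "quantify_table",
    "read_peak_table",
    "write_measures",
    "DEFAULT_CV_THRESHOLD",
    "DEFAULT_DETECTION_FLOOR",
    "DEFAULT_MIN_SEPARATION",
    "DEFAULT_MAX_RESIDUAL_FRACTION",
]

#: Replicate CV above which a sample is excluded from analysis.
DEFAULT_CV_THRESHOLD = 0.15
#: Peak height (RFU) below which a peak is treated as undetected.
DEFAULT_DETECTION_FLOOR = 50.0
#: Minimum allele size separation (bp) for a heterozygous call: one CAG unit.
DEFAULT_MIN_SEPARATION = 3.0
#: Maximum MspI residual peak height, as a fraction of the mean mock height,
#: compatible with complete digestion.
DEFAULT_MAX_RESIDUAL_FRACTION = 0.1

QC_PASS = "pass"
QC_CV_FAIL = "cv_fail"
QC_HOMOZYGOUS = "homozygous_uninformative"
QC_DIGESTION_FAIL = "digestion_fail"
QC_ASSAY_FAIL = "assay_fail"

QC_STATUSES = (QC_PASS, QC_CV_FAIL, QC_HOMOZYGOUS, QC_DIGESTION_FAIL, QC_ASSAY_FAIL)


class AssayFailure(ValueError):
    """Raised when a replicate is unusable (e.g. absent mock amplification)."""


class DigestionFailure(ValueError):
    """Raised when both HpaII peaks are below the detection floor.

    With both mock alleles present, a fully empty HpaII lane means the
    digest/re-amplification failed rather than that the sample is skewed.
    """


@dataclass(frozen=True)
class PeakPair:
    """Peak sizes and heights for the two AR alleles in one digest lane.

    Allele 1 is by convention the shorter fragment.  Equal sizes encode an
    apparently homozygous sample (a single peak), which is representable so
    that informativeness can be decided downstream rather than at parse time.
    """

    allele1_size: float
    allele2_size: float
    allele1_height: float
    allele2_height: float

    def __post_init__(self) -> None:
        if self.allele1_height < 0 or self.allele2_height < 0:
            raise ValueError("peak heights must be non-negative")
        if self.allele1_size > self.allele2_size:
            raise ValueError(
                "allele 1 must be the shorter fragment "
                f"(got {self.allele1_size} > {self.allele2_size})"
            )

    @property
    def separation(self) -> float:
        """Fragment-size separation between the two alleles (bp)."""
        return self.allele2_size - self.allele1_size

    def swapped(self) -> "PeakPair":
        """Return the pair with allele labels exchanged (for symmetry tests)."""
        return PeakPair(
            allele1_size=self.allele1_size,
            allele2_size=self.allele2_size,
            allele1_height=self.allele2_height,
            allele2_height=self.allele1_height,
        )


@dataclass
class SampleAssay:
    """One individual's HUMARA peak measurements across the three digests."""

    sample_id: str
    mock_replicates: list[PeakPair]
    hpaii_replicates: list[PeakPair]
    mspi_peaks: PeakPair | None = None

    def __post_init__(self) -> None:
        if len(self.mock_replicates) != len(self.hpaii_replicates):
            raise ValueError(
                f"sample {self.sample_id}: mock and HpaII replicate lists must "
                f"have equal length ({len(self.mock_replicates)} vs "
                f"{len(self.hpaii_replicates)})"
            )
        if len(self.mock_replicates) < 1:
            raise ValueError(f"sample {self.sample_id}: at least one replicate required")


@dataclass
class XCIMeasure:
    """Quantified XCI percentage for one sample, with QC annotations."""

    sample_id: str
    replicate_xci: list[float] = field(default_factory=list)
    xci_mean: float = math.nan
    xci_folded: float = math.nan
    cv: float = math.nan
    qc_status: str = QC_ASSAY_FAIL

    @property
    def passed(self) -> bool:
        return self.qc_status == QC_PASS


def replicate_xci(
    mock: PeakPair,
    hpaii: PeakPair,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
) -> float:
    """XCI percentage for a single mock/HpaII replicate pair.

    Computes Rm and Rh as allele-1/allele-2 peak-height ratios, Rn = Rh/Rm,
    and returns ``100 * Rn / (Rn + 1)``.

    Peak heights below ``detection_floor`` are clamped to the floor, with one
    exception: an HpaII allele below the floor while the other HpaII allele
    is detected reads as complete skew, returning exactly 0.0 (allele 1
    absent) or 100.0 (allele 2 absent).

    Raises
    ------
    AssayFailure
        If either mock peak height is zero (no amplification baseline).
    DigestionFailure
        If both HpaII peaks fall below the detection floor.
    """
    if mock.allele1_height <= 0 or mock.allele2_height <= 0:
        raise AssayFailure("mock digest peak height is zero; no amplification baseline")

    h1, h2 = hpaii.allele1_height, hpaii.allele2_height
    if h1 < detection_floor and h2 < detection_floor:
        raise DigestionFailure(
            "both HpaII peaks below detection floor; digest/amplification failure"
        )
    if h1 < detection_floor:
        return 0.0
    if h2 < detection_floor:
        return 100.0

    m1 = max(mock.allele1_height, detection_floor)
    m2 = max(mock.allele2_height, detection_floor)
    rm = m1 / m2
    rh = h1 / h2
    rn = rh / rm
    if not math.isfinite(rn):
        raise AssayFailure(f"non-finite normalised ratio Rn={rn!r}")
    return 100.0 * rn / (rn + 1.0)


def fold_xci(x):
    """Collapse XCI% from [0, 100] onto [50, 100].

    The direction of skew (which parental X is preferentially inactivated)
    carries no information, so 30% and 70% are the same degree of skew.
    Accepts scalars or arrays; idempotent.
    """
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("XCI percentage must lie in [0, 100]")
    folded = np.maximum(arr, 100.0 - arr)
    if np.isscalar(x) or arr.ndim == 0:
        return float(folded)
    return folded


def is_informative(
    assay: SampleAssay,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
) -> bool:
    """Whether the sample is heterozygous for the AR CAG repeat.

    Requires two distinct allele peaks separated by at least
    ``min_separation`` bp (default one CAG unit, 3 bp) and both detected, in
    every mock replicate.  Homozygous samples yield a single peak and cannot
    report an allele ratio.
    """
    for rep in assay.mock_replicates:
        if rep.separation < min_separation:
            return False
        if rep.allele1_height < detection_floor or rep.allele2_height < detection_floor:
            return False
    return True


def digestion_control_ok(
    assay: SampleAssay,
    max_residual_fraction: float = DEFAULT_MAX_RESIDUAL_FRACTION,
) -> bool:
    """Check the MspI digestion-efficiency control.

    MspI cuts regardless of methylation, so a complete digest leaves no
    amplifiable template: residual MspI peaks above
    ``max_residual_fraction`` times the mean mock peak height indicate
    incomplete digestion.  When the control lane is absent the check passes
    with a logged warning.
    """
    if assay.mspi_peaks is None:
        logger.warning(
            "sample %s: MspI digestion control absent; skipping check", assay.sample_id
        )
        return True
    mock_heights = [
        h
        for rep in assay.mock_replicates
        for h in (rep.allele1_height, rep.allele2_height)
    ]
    mock_mean = float(np.mean(mock_heights))
    if mock_mean <= 0:
        return False
    residual = max(assay.mspi_peaks.allele1_height, assay.mspi_peaks.allele2_height)
    return residual <= max_residual_fraction * mock_mean


def quantify_sample(
    assay: SampleAssay,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    max_residual_fraction: float = DEFAULT_MAX_RESIDUAL_FRACTION,
) -> XCIMeasure:
    """Quantify XCI for one sample with full QC.

    Per-replicate XCI percentages are computed from index-paired mock/HpaII
    replicates; the sample summary is their arithmetic mean, the replicate
    coefficient of variation (sample SD / mean) is the QC statistic, and the
    folded value is ``max(mean, 100 - mean)``.

    QC status precedence (highest wins):
    ``assay_fail`` (no amplification, or fewer than 2 usable replicates) >
    ``homozygous_uninformative`` > ``digestion_fail`` >
    ``cv_fail`` (CV above ``cv_threshold``) > ``pass``.
    """
    measure = XCIMeasure(sample_id=assay.sample_id)

    # assay-level amplification check: a sample whose mock lanes show no
    # signal is a failed assay regardless of genotype
    amplified = sum(
        max(m.allele1_height, m.allele2_height) >= detection_floor
        for m in assay.mock_replicates
    )
    if amplified < 2:
        measure.qc_status = QC_ASSAY_FAIL
        return measure

    # homozygotes present a single peak; no allele ratio is defined
    if not is_informative(assay, min_separation=min_separation, detection_floor=detection_floor):
        measure.qc_status = QC_HOMOZYGOUS
        return measure

    values: list[float] = []
    for mock, hp in zip(assay.mock_replicates, assay.hpaii_replicates):
        try:
            values.append(replicate_xci(mock, hp, detection_floor=detection_floor))
        except (AssayFailure, DigestionFailure) as exc:
            logger.debug("sample %s: replicate dropped (%s)", assay.sample_id, exc)
    measure.replicate_xci = values
    if len(values) < 2:
        measure.qc_status = QC_ASSAY_FAIL
        return measure

    arr = np.asarray(values, dtype=float)
    measure.xci_mean = float(arr.mean())
    measure.xci_folded = fold_xci(measure.xci_mean)
    sd = float(arr.std(ddof=1))
    measure.cv = 0.0 if sd == 0.0 else sd / measure.xci_mean

    if not digestion_control_ok(assay, max_residual_fraction=max_residual_fraction):
        measure.qc_status = QC_DIGESTION_FAIL
    elif measure.cv > cv_threshold:
        measure.qc_status = QC_CV_FAIL
    else:
        measure.qc_status = QC_PASS
    return measure


def quantify_table(
    assays: Iterable[SampleAssay],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    max_residual_fraction: float = DEFAULT_MAX_RESIDUAL_FRACTION,
) -> pd.DataFrame:
    """Quantify a collection of assays into a tidy per-sample table."""
    rows = []
    for assay in assays:
        m = quantify_sample(
            assay,
            cv_threshold=cv_threshold,
            detection_floor=detection_floor,
            min_separation=min_separation,
            max_residual_fraction=max_residual_fraction,
        )
        rows.append(
            {
                "sample_id": m.sample_id,
                "n_replicates": len(m.replicate_xci),
                "xci_mean": m.xci_mean,
                "xci_folded": m.xci_folded,
                "cv": m.cv,
                "qc_status": m.qc_status,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table I/O

_PEAK_COLUMNS = [
    "sample_id",
    "digest",
    "replicate",
    "allele1_size",
    "allele1_height",
    "allele2_size",
    "allele2_height",
]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_peak_table(path: str | Path) -> list[SampleAssay]:
    """Read a peak table (TSV/CSV) into :class:`SampleAssay` objects.

    Expected columns: ``sample_id``, ``digest`` (one of mock/hpaii/mspi),
    ``replicate``, ``allele1_size``, ``allele1_height``, ``allele2_size``,
    ``allele2_height``.  Replicates pair by index between the mock and HpaII
    digests.
    """
    df = _read_delimited(path)
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"peak table {path} contains no rows")

    def _pair(row) -> PeakPair:
        return PeakPair(
            allele1_size=float(row.allele1_size),
            allele2_size=float(row.allele2_size),
            allele1_height=float(row.allele1_height),
            allele2_height=float(row.allele2_height),
        )

    assays: list[SampleAssay] = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        by_digest = {d: g.sort_values("replicate") for d, g in grp.groupby("digest")}
        mock = [_pair(r) for r in by_digest.get("mock", pd.DataFrame()).itertuples()]
        hpaii = [_pair(r) for r in by_digest.get("hpaii", pd.DataFrame()).itertuples()]
        mspi_df = by_digest.get("mspi")
        mspi = _pair(next(mspi_df.itertuples())) if mspi_df is not None and len(mspi_df) else None
        assays.append(
            SampleAssay(
                sample_id=str(sample_id),
                mock_replicates=mock,
                hpaii_replicates=hpaii,
                mspi_peaks=mspi,
            )
        )
    return assays


def write_measures(measures: pd.DataFrame, path: str | Path) -> None:
    """Write a quantified XCI table to TSV/CSV (by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    measures.to_csv(path, sep=sep, index=False)
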