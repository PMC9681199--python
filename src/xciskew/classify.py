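"""Cohort-level categorical XCI-skew variable.

The folded XCI distribution of a cohort is summarised by its mean and
standard deviation, and individuals are binned by how many SDs above the
mean their folded XCI value lies: below 1 SD is random XCI (0), between 1
and 2 SDs is skewed XCI (1), and at or beyond 2 SDs is extreme skew (2).
On the cohort this package was designed around, the 1-SD and 2-SD cuts fall
near 75% and 91% folded XCI; the cuts are cohort-dependent and are fitted
once on all QC-passing samples, then frozen for every subgroup analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SkewCategory",
    "SkewThresholds",
    "fit_thresholds",
    "classify",
    "combine_for_survival",
    "save_thresholds",
    "load_thresholds",
]

MIN_COHORT_SIZE = 30


class SkewCategory(IntEnum):
    RANDOM = 0
    SKEWED = 1
    EXTREME = 2

    @property
    def label(self) -> str:
        return {0: "random", 1: "skewed", 2: "extreme"}[int(self)]


@dataclass(frozen=True)
class SkewThresholds:
    """Fitted cohort thresholds for the categorical skew variable.

    ``cut1_xci``/``cut2_xci`` are the XCI% equivalents of 1 and 2 SDs above
    the mean; ``mode`` records whether the moments were taken on the folded
    50-100 scale (default) or on the unfolded 0-100 scale with |z| used for
    classification.
    """

    mean: float
    sd: float
    cut1_xci: float
    cut2_xci: float
    n: int
    mode: str = "folded"

    def zscore(self, value):
        z = (np.asarray(value, dtype=float) - self.mean) / self.sd
        if self.mode == "absolute":
            z = np.abs(z)
        return z


def fit_thresholds(
    values,
    mode: str = "folded",
    min_n: int = MIN_COHORT_SIZE,
) -> SkewThresholds:
    """Fit the cohort mean/SD and derive the 1-SD and 2-SD XCI% cutpoints.

    Parameters
    ----------
    values
        QC-passing XCI percentages: folded (50-100) in ``mode="folded"``,
        unfolded (0-100) in ``mode="absolute"``.
    mode
        ``"folded"`` (default): z-scores of the folded distribution, upper
        tail.  ``"absolute"``: z-scores of the unfolded distribution with
        absolute values taken at classification time.
    """
    if mode not in ("folded", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise ValueError(
            f"need at least {min_n} QC-passing values to fit cohort thresholds "
            f"(got {arr.size}); a smaller cohort cannot anchor the SD-based cuts"
        )
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate XCI distribution: zero standard deviation")
    return SkewThresholds(
        mean=mean,
        sd=sd,
        cut1_xci=mean + sd,
        cut2_xci=mean + 2 * sd,
        n=int(arr.size),
        mode=mode,
    )


def classify(folded, thresholds: SkewThresholds):
    """Assign skew categories from folded XCI values.

    z < 1 is random (0); 1 <= z < 2 is skewed (1); z >= 2 is extreme (2),
    with boundaries inclusive on the upper category.  Vectorised; scalar
    input returns a :class:`SkewCategory`.
    """
    z = thresholds.zscore(folded)
    cats = np.where(z >= 2, 2, np.where(z >= 1, 1, 0))
    if np.ndim(folded) == 0:
        return SkewCategory(int(cats))
    return cats.astype(int)


def combine_for_survival(category):
    """Collapse the 3-level category to the binary skew flag (0 vs 1/2).

    Skewed and extreme-skew groups are pooled for the survival analyses,
    where event counts are too small to resolve them separately.
    """
    arr = np.asarray(category, dtype=int)
    flag = (arr >= 1).astype(int)
    if np.ndim(category) == 0:
        return int(flag)
    return flag


def save_thresholds(thresholds: SkewThresholds, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(thresholds), sort_keys=False))


def load_thresholds(path: str | Path) -> SkewThresholds:
    data = yaml.safe_load(Path(path).read_text())
    return SkewThresholds(**data)
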