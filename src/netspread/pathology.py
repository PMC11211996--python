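"""Regional pathology preparation.

Tau-PET SUVR vectors are min-max scaled onto [0, 1]; atrophy is scored as
z-scores against age-matched healthy controls and squashed through the
logistic function.  Cohort filters implement the amyloid-positivity cut-off
(summary SUVR > 1.11) and the elevated-tau rule (medial-temporal SUVR more
than two standard deviations above the amyloid-negative mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import is_cortical

AMYLOID_SUVR_CUTOFF = 1.11


@dataclass
class RegionalPattern:
    """Per-region pathology values on [0, 1] with region labels."""

    values: np.ndarray
    region_labels: list[str]
    kind: str = "simulated"  # tau | atrophy | simulated

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.region_labels):
            raise ValueError("values and region_labels length mismatch")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(v)):
            raise ValueError("pattern contains non-finite values")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("pattern values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        self.region_labels = list(self.region_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region": self.region_labels, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "simulated") -> "RegionalPattern":
        df = pd.read_csv(path)
        return cls(df["value"].to_numpy(float), [str(r) for r in df["region"]], kind)


@dataclass
class SubjectCohort:
    """Per-subject regional raw values plus demographics.

    ``data`` holds one row per subject with region columns plus ``age``,
    ``group`` and optionally ``amyloid_suvr``.
    """

    data: pd.DataFrame
    region_labels: list[str]

    def __post_init__(self) -> None:
        missing = [l for l in self.region_labels if l not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table lacks region columns: {missing[:3]}")

    @property
    def regional_values(self) -> np.ndarray:
        return self.data[self.region_labels].to_numpy(float)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(float)


def minmax_scale(raw, region_labels: list[str] | None = None,
                 kind: str = "tau") -> RegionalPattern:
    """Min-max scale a raw regional vector onto [0, 1]."""
    v = np.asarray(raw, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot min-max scale a constant vector")
    labels = region_labels if region_labels is not None else [
        f"region_{i}" for i in range(v.size)
    ]
    return RegionalPattern((v - lo) / (hi - lo), labels, kind)


def atrophy_zscores(
    subject_volumes,
    controls: SubjectCohort,
    subject_age: float,
    age_window: float = 5.0,
    min_controls: int = 10,
) -> np.ndarray:
    """Regional atrophy z-scores against age-matched controls.

    The sign convention is z = (control mean - subject) / control sd, so
    larger z means more atrophy (smaller volume).  Controls within
    ``age_window`` years of the subject's age are used.
    """
    v = np.asarray(subject_volumes, dtype=float)
    in_window = np.abs(controls.ages - subject_age) <= age_window
    if in_window.sum() < min_controls:
        raise ValueError(
            f"only {int(in_window.sum())} controls within +/-{age_window} years "
            f"of age {subject_age}; need >= {min_controls}"
        )
    ctrl = controls.regional_values[in_window]
    mean = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    zero = sd < 1e-15
    if np.any(zero):
        bad = [controls.region_labels[i] for i in np.nonzero(zero)[0][:3]]
        raise ValueError(f"zero control variance in region(s) {bad}")
    return (mean - v) / sd


def logistic_map(z, region_labels: list[str] | None = None) -> RegionalPattern:
    """Map reals onto [0, 1] with the standard logistic 1/(1+exp(-z))."""
    z = np.asarray(z, dtype=float)
    vals = 1.0 / (1.0 + np.exp(-z))
    labels = region_labels if region_labels is not None else [
        f"region_{i}" for i in range(z.size)
    ]
    return RegionalPattern(vals, labels, "atrophy")


def group_average_pattern(patterns: list[RegionalPattern]) -> RegionalPattern:
    """Regionwise mean of identically-labelled patterns."""
    ref = patterns[0]
    for p in patterns[1:]:
        if p.region_labels != ref.region_labels:
            raise ValueError("region labels differ across subjects")
    mean = np.mean([p.values for p in patterns], axis=0)
    return RegionalPattern(mean, ref.region_labels, ref.kind)


def amyloid_positive(summary_suvr: float) -> bool:
    """Amyloid-beta positivity: summary cortical SUVR strictly above 1.11."""
    if summary_suvr <= 0:
        raise ValueError("SUVR must be positive")
    return bool(summary_suvr > AMYLOID_SUVR_CUTOFF)


def elevated_tau(subject_mtl_suvr: float, negatives) -> bool:
    """Elevated tau: medial-temporal SUVR strictly above the amyloid-negative
    mean plus two sample standard deviations."""
    ref = np.asarray(negatives, dtype=float)
    if ref.size < 2:
        raise ValueError("need >= 2 amyloid-negative reference values")
    sd = ref.std(ddof=1)
    if sd < 1e-15:
        raise ValueError("amyloid-negative reference has zero variance")
    return bool(subject_mtl_suvr > ref.mean() + 2.0 * sd)


def subset_cortical(p: RegionalPattern) -> RegionalPattern:
    """Restrict a pattern to cortical regions, preserving order."""
    keep = [i for i, l in enumerate(p.region_labels) if is_cortical(l)]
    if not keep:
        raise ValueError("no cortical labels present")
    return RegionalPattern(
        p.values[keep], [p.region_labels[i] for i in keep], p.kind
    )
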