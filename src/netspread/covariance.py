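"""Covariance-based connectome construction from subject-level measures.

Morphological covariance networks correlate covariate-adjusted regional
cortical thickness across subjects; functional and microstructural networks
are partial correlations between regional profiles, either conditioning on
all remaining regions (precision-matrix formulation) or on the cortex-wide
grand-mean profile only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from .connectome import Connectome


@dataclass
class SubjectMeasureTable:
    """Subjects x regions measures (e.g. cortical thickness) with covariates."""

    values: np.ndarray  # subjects x regions
    region_labels: list[str]
    age: np.ndarray
    sex: np.ndarray  # 0/1 coding

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        n, r = self.values.shape
        if r != len(self.region_labels):
            raise ValueError("region label count does not match value columns")
        if not (np.all(np.isfinite(self.values)) and np.all(np.isfinite(self.age))):
            raise ValueError("table contains non-finite values")
        if n < 9:  # 5 design columns + 4
            raise ValueError(f"need at least 9 subjects, got {n}")

    @classmethod
    def from_csv(cls, path) -> "SubjectMeasureTable":
        df = pd.read_csv(path)
        regions = [c for c in df.columns if c not in ("age", "sex", "subject")]
        return cls(
            df[regions].to_numpy(float), regions,
            df["age"].to_numpy(float), df["sex"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.region_labels)
        df["age"] = self.age
        df["sex"] = self.sex
        df.to_csv(path, index=False)


@dataclass
class ProfileTable:
    """Regions x samples profiles (fMRI time courses or depth-wise intensities)."""

    series: np.ndarray  # regions x samples
    region_labels: list[str]
    grand_mean_profile: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[0] != len(self.region_labels):
            raise ValueError("region label count does not match series rows")
        if self.series.shape[1] < 3:
            raise ValueError("need at least 3 samples per region")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")
        if self.grand_mean_profile is None:
            self.grand_mean_profile = self.series.mean(axis=0)

    @classmethod
    def from_csv(cls, path) -> "ProfileTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), [str(i) for i in df.index])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.series, index=self.region_labels).to_csv(path)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of y on the design X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def morphological_covariance(t: SubjectMeasureTable) -> Connectome:
    """Morphological covariance network from regional cortical thickness.

    At every region, thickness is regressed on intercept, age, sex, the
    age-sex interaction, and each subject's mean thickness over all regions;
    edges are the Pearson correlations of the residuals across subjects.
    Negative correlations are retained here and zeroed downstream by the
    connectome-conditioning step.
    """
    mean_thick = t.values.mean(axis=1)
    X = np.column_stack([
        np.ones(len(t.age)), t.age, t.sex, t.age * t.sex, mean_thick,
    ])
    names = ["intercept", "age", "sex", "age*sex", "mean_measure"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the first column that adds no rank
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"collinear covariate: {names[j]}")
        raise ValueError("rank-deficient covariate design")
    resid = _residualize(t.values, X)
    r = np.corrcoef(resid, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return Connectome(r, t.region_labels, "morphological")


def _pcorr_from_precision(P: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(P))
    r = -P / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def partial_correlation_network(
    p: ProfileTable, control_grand_mean: bool = False
) -> Connectome:
    """Partial-correlation connectome from regional profiles.

    With ``control_grand_mean=False`` every pair is conditioned on all
    remaining regions via the precision matrix; Ledoit-Wolf shrinkage is used
    when samples < 5 x regions, and a small ridge is added if the covariance
    is singular.  With ``control_grand_mean=True`` each pair is conditioned
    only on the cortex-wide grand-mean profile.
    """
    X = p.series.T  # samples x regions
    n_samples, n_regions = X.shape
    if n_regions < 3:
        raise ValueError("need at least 3 regions")
    if np.any(X.std(axis=0) < 1e-15):
        raise ValueError("constant series in at least one region")

    if control_grand_mean:
        G = np.column_stack([np.ones(n_samples), p.grand_mean_profile])
        resid = _residualize(X, G)
        sd = resid.std(axis=0)
        if np.any(sd < 1e-15):
            raise ValueError("a regional profile equals the grand mean exactly")
        r = np.corrcoef(resid, rowvar=False)
        np.fill_diagonal(r, 0.0)
        return Connectome((r + r.T) / 2.0, p.region_labels, "microstructural")

    if n_samples < 5 * n_regions:
        cov = LedoitWolf(assume_centered=False).fit(X).covariance_
    else:
        cov = np.cov(X, rowvar=False)
    # ridge fallback for (near-)singular covariance
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        cov = cov + 1e-8 * np.trace(cov) / n_regions * np.eye(n_regions)
    P = np.linalg.inv(cov)
    return Connectome(_pcorr_from_precision(P), p.region_labels, "functional")
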