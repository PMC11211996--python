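"""Network diffusion dynamics: graph Laplacian, seeding, and propagation.

The model is the linear system dx/dt = -beta * H * x with H the random-walk
graph Laplacian of a row-normalised connectome, solved in closed form as
x(t) = expm(-beta * H * t) x0.  Pathology is seeded bilaterally: x0 is one at
the left and right instances of the seed region and zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .connectome import Connectome, row_normalize
from .labels import base_region, hemisphere


@dataclass
class DiffusionOperator:
    """Graph Laplacian of a conditioned connectome plus diffusivity.

    ``H`` has zero row sums (isolated-node rows are all-zero, so isolated
    regions hold their value), and its eigenvalue of smallest real part is 0.
    An eigendecomposition is cached lazily so that repeated simulations over
    dense time grids and many seed vectors cost a single factorisation.
    """

    H: np.ndarray
    region_labels: list[str]
    beta: float = 1.0
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not np.all(np.isfinite(self.H)):
            raise ValueError("H contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def _eigendecomposition(self):
        if self._eig is None:
            w, V = np.linalg.eig(self.H)
            try:
                Vinv = np.linalg.inv(V)
                ok = np.linalg.cond(V) < 1e10
            except np.linalg.LinAlgError:
                Vinv, ok = None, False
            self._eig = (w, V, Vinv, ok)
        return self._eig

    def propagate(self, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Raw states expm(-beta H t) x0 at each time; shape (T, n)."""
        times = np.asarray(times, dtype=float)
        bt = self.beta * times  # beta and t enter only through their product
        w, V, Vinv, ok = self._eigendecomposition()
        if ok:
            coeff = Vinv @ x0.astype(complex)
            # (T, n) spectral weights; eigenvalues of H are real for
            # row-stochastic P but kept complex for safety
            phases = np.exp(-np.outer(bt, w))
            states = np.real((phases * coeff) @ V.T)
        else:  # defective/ill-conditioned basis: exact expm per timepoint
            states = np.empty((times.size, self.n_regions))
            for i, s in enumerate(bt):
                states[i] = scipy.linalg.expm(-s * self.H) @ x0
        return states


def graph_laplacian(
    c: Connectome, beta: float = 1.0, kind: str = "random-walk"
) -> DiffusionOperator:
    """Laplacian of the row-sum-normalised connectome.

    ``kind='random-walk'`` (default) gives H = I - D^-1 C; ``kind='symmetric'``
    gives H = I - D^-1/2 C D^-1/2.  Rows of isolated nodes are zeroed so those
    regions carry no dynamics.
    """
    w = np.clip(c.weights, 0.0, None)
    deg = w.sum(axis=1)
    pos = deg > 0
    n = c.n_regions
    if kind == "random-walk":
        P = row_normalize(c)
        H = -P
        H[pos, pos] += 1.0
    elif kind == "symmetric":
        dinv_sqrt = np.zeros(n)
        dinv_sqrt[pos] = 1.0 / np.sqrt(deg[pos])
        H = -(dinv_sqrt[:, None] * w * dinv_sqrt[None, :])
        H[pos, pos] += 1.0
    else:
        raise ValueError(f"unknown Laplacian kind {kind!r}")
    return DiffusionOperator(H, list(c.region_labels), beta)


@dataclass
class SeedVector:
    """Bilateral seed: unit pathology at both hemispheric instances."""

    x0: np.ndarray
    seed_region: str
    region_labels: list[str]


def make_seed(region_labels: list[str], seed_region: str) -> SeedVector:
    """Unit mass at ``lh_<seed_region>`` and ``rh_<seed_region>``."""
    hits = [
        i
        for i, l in enumerate(region_labels)
        if base_region(l) == seed_region and hemisphere(l) in ("lh", "rh")
    ]
    if len(hits) != 2:
        raise ValueError(
            f"seed region {seed_region!r} must appear in both hemispheres "
            f"(found {len(hits)} instances)"
        )
    x0 = np.zeros(len(region_labels))
    x0[hits] = 1.0
    return SeedVector(x0, seed_region, list(region_labels))


def default_time_grid(
    t_min: float = 1e-3, t_max: float = 1e3, n_times: int = 501
) -> np.ndarray:
    """Geometric grid from t_min to t_max with t = 0 prepended (n_times total)."""
    return np.concatenate([[0.0], np.geomspace(t_min, t_max, n_times - 1)])


_DEGENERATE_TOL = 1e-12


def _minmax_rows(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row min-max rescaling to [0, 1]; near-constant rows are flagged
    degenerate and filled with 0.5."""
    lo = raw.min(axis=1, keepdims=True)
    hi = raw.max(axis=1, keepdims=True)
    span = (hi - lo).ravel()
    degenerate = span < _DEGENERATE_TOL
    norm = np.full_like(raw, 0.5)
    ok = ~degenerate
    norm[ok] = (raw[ok] - lo[ok]) / (hi[ok] - lo[ok])
    return norm, degenerate


@dataclass
class TrajectorySet:
    """Diffusion snapshots on a time grid.

    ``raw_states`` holds expm(-beta H t) x0; ``states`` holds the
    per-timepoint min-max normalisation onto [0, 1] used for comparison with
    measured pathology.  Near-constant (degenerate) snapshots are flagged.
    """

    times: np.ndarray
    states: np.ndarray
    raw_states: np.ndarray
    degenerate: np.ndarray
    region_labels: list[str]

    def subset(self, labels: list[str]) -> "TrajectorySet":
        """Restrict to ``labels`` (in that order) and re-normalise rows."""
        idx = {l: i for i, l in enumerate(self.region_labels)}
        missing = [l for l in labels if l not in idx]
        if missing:
            raise ValueError(f"labels absent from trajectory: {missing[:3]}")
        cols = [idx[l] for l in labels]
        raw = self.raw_states[:, cols]
        norm, degenerate = _minmax_rows(raw)
        return TrajectorySet(self.times, norm, raw, degenerate, list(labels))


def simulate(op: DiffusionOperator, x0: SeedVector, times) -> TrajectorySet:
    """Propagate a seed over the diffusion operator at the given times."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if op.region_labels != x0.region_labels:
        raise ValueError("operator and seed label sets differ")
    raw = op.propagate(x0.x0, times)
    norm, degenerate = _minmax_rows(raw)
    return TrajectorySet(times, norm, raw, degenerate, list(op.region_labels))
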