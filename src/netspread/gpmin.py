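"""Gaussian-process minimisation over a box.

A sequential model-based optimiser: an initial batch of uniform random
evaluations, then iterations in which a Gaussian-process surrogate (Matern
5/2 kernel) is fitted to all evaluations so far and the next point maximises
expected improvement over a random candidate set.  Deterministic for a fixed
random generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

import warnings


@dataclass
class GPMinResult:
    """Best point, best value, and the full evaluation trace."""

    x: np.ndarray
    fun: float
    x_iters: np.ndarray
    func_vals: np.ndarray


def gp_minimize(
    func,
    bounds: list[tuple[float, float]],
    n_random: int = 300,
    n_iter: int = 500,
    rng: np.random.Generator | int | None = 0,
    n_candidates: int = 2000,
    xi: float = 0.01,
    x0: list | None = None,
) -> GPMinResult:
    """Minimise ``func`` over a box with a GP surrogate and EI acquisition.

    Parameters
    ----------
    func : callable
        Maps a 1-D array within ``bounds`` to a scalar.
    bounds : list of (low, high)
        Box constraints, one pair per dimension.
    n_random : int
        Uniform random evaluations before the surrogate takes over.
    n_iter : int
        Surrogate-guided evaluations.
    rng : Generator, int or None
        Randomness source; fixing it makes the run bit-reproducible.
    n_candidates : int
        Random candidate points scored by expected improvement per iteration.
    xi : float
        Exploration margin in the expected-improvement criterion.
    x0 : list of arrays, optional
        Points evaluated before the random starts (counted on top of the
        budget); useful to guarantee known vertices are in the design.
    """
    rng = np.random.default_rng(rng)
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    dim = lo.size
    if n_random < 1:
        raise ValueError("need at least one random start")

    X = rng.uniform(lo, hi, size=(n_random, dim))
    if x0:
        X = np.vstack([np.atleast_2d(np.asarray(x0, float)), X])
    y = np.array([func(x) for x in X], float)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(dim, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    )
    for _ in range(n_iter):
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-8,
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y)
        cand = rng.uniform(lo, hi, size=(n_candidates, dim))
        mu, sd = gp.predict(cand, return_std=True)
        best = y.min()
        sd = np.maximum(sd, 1e-12)
        z = (best - mu - xi) / sd
        ei = (best - mu - xi) * norm.cdf(z) + sd * norm.pdf(z)
        x_next = cand[int(np.argmax(ei))]
        X = np.vstack([X, x_next])
        y = np.append(y, func(x_next))

    i = int(np.argmin(y))
    return GPMinResult(x=X[i].copy(), fun=float(y[i]), x_iters=X, func_vals=y)
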