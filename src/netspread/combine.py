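"""Model selection over connectomes: seed/threshold grid search,
Gaussian-process optimisation of multimodal combination weights, rewired-null
benchmarking, cross-validation, and subsample stability.

The combination model searches the unit hypercube of raw modality weights,
normalising each point onto the simplex, so the convex hull of the input
connectomes (including every single modality as a one-hot vertex) is the
feasible set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import (
    CombinationWeights,
    Connectome,
    combine_connectomes,
    group_average,
    proportional_threshold,
    rewire,
    zero_negative_weights,
)
from .diffusion import default_time_grid, graph_laplacian, make_seed, simulate
from .gpmin import gp_minimize
from .model import NDMResults, fit_time, run_pipeline
from .pathology import RegionalPattern, group_average_pattern
from .utils import child_seeds


@dataclass
class GridSearchResult:
    """Exhaustive seed x threshold evaluation of a single connectome."""

    table: pd.DataFrame  # columns: seed, threshold, sse, r_max, t_opt
    best_seed: str
    best_threshold: float
    best_fit: NDMResults

    def summary(self) -> str:
        head = self.table.sort_values("sse").head(10).to_string(index=False)
        return (
            f"Grid search: best seed={self.best_seed!r} "
            f"threshold={self.best_threshold} "
            f"r_max={self.best_fit.r_max:.4f}\n{head}"
        )


def grid_search(
    connectome: Connectome,
    seeds: list[str],
    thresholds: list[float],
    measured: RegionalPattern,
    beta: float = 1.0,
    times: np.ndarray | None = None,
    laplacian_kind: str = "random-walk",
) -> GridSearchResult:
    """Evaluate every (seed, threshold) cell; best cell minimises SSE.

    The diffusion operator is factorised once per threshold and shared across
    seeds, which only change the initial condition.
    """
    if not seeds or not thresholds:
        raise ValueError("seed and threshold grids must be non-empty")
    t_grid = default_time_grid() if times is None else np.asarray(times, float)
    rows = []
    best = None
    for thr in thresholds:
        c = proportional_threshold(zero_negative_weights(connectome), thr)
        op = graph_laplacian(c, beta, laplacian_kind)  # one factorisation
        for seed in seeds:
            x0 = make_seed(op.region_labels, seed)
            traj = simulate(op, x0, t_grid).subset(measured.region_labels)
            res = fit_time(traj, measured)
            res.seed_region, res.threshold = seed, thr
            rows.append(
                dict(seed=seed, threshold=thr, sse=res.sse_opt,
                     r_max=res.r_max, t_opt=res.t_opt)
            )
            if best is None or res.sse_opt < best.sse_opt:
                best = res
    table = pd.DataFrame(rows)
    return GridSearchResult(table, best.seed_region, best.threshold, best)


@dataclass
class CombinationResults:
    """Optimised multimodal combination.

    ``weights`` lives on the simplex over the modality tags; ``fit`` is the
    diffusion-model fit of the combined connectome at the returned seed, and
    ``trace`` records every (raw weight vector, SSE) evaluation of the
    optimiser for audit.
    """

    weights: CombinationWeights
    seed_region: str
    fit: NDMResults
    trace: list = field(repr=False)
    rng_seed: int | None = None
    per_seed_best: dict | None = None

    def summary(self) -> str:
        lines = [
            "Combined-connectome optimisation",
            "=" * 44,
            f"{'seed region':<26}{self.seed_region:>18}",
            f"{'r_max':<26}{self.fit.r_max:>18.4f}",
            f"{'SSE':<26}{self.fit.sse_opt:>18.6g}",
            f"{'t_opt':<26}{self.fit.t_opt:>18.6g}",
            "-" * 44,
        ]
        for mod, lam in sorted(
            self.weights.lambdas.items(), key=lambda kv: -kv[1]
        ):
            lines.append(f"  lambda[{mod:<18}]{lam:>16.3f}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "weights": {k: float(v) for k, v in self.weights.lambdas.items()},
            "seed_region": self.seed_region,
            "rng_seed": self.rng_seed,
            **self.fit.to_dict(),
        }

    def plot_weights(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mods = list(self.weights.lambdas)
        ax.bar(mods, [self.weights.lambdas[m] for m in mods])
        ax.set_ylabel("combination weight")
        ax.set_ylim(0, 1)
        return ax


class ConnectomeCombinationModel:
    """Optimise simplex weights of a multimodal connectome combination.

    Each input connectome should already be thresholded at its
    modality-specific optimum.  For every candidate seed region an
    independent Gaussian-process minimisation (``n_random`` uniform starts
    followed by ``n_iter`` surrogate-guided iterations) searches raw weights
    in [0, 1]^K; every evaluation normalises onto the simplex, builds the
    combined connectome, runs the diffusion-model time scan, and returns the
    SSE at the optimal time.  The global best over seeds is returned.
    """

    def __init__(
        self,
        connectomes: list[Connectome],
        measured: RegionalPattern,
        seeds: list[str],
        n_random: int = 300,
        n_iter: int = 500,
        beta: float = 1.0,
        times: np.ndarray | None = None,
        laplacian_kind: str = "random-walk",
    ) -> None:
        if len(connectomes) < 2:
            raise ValueError("need at least 2 connectomes to combine")
        if n_random + n_iter < len(connectomes) + 1:
            raise ValueError("optimiser budget too small for the dimension")
        self.connectomes = connectomes
        self.modalities = [c.modality for c in connectomes]
        self.measured = measured
        self.seeds = list(seeds)
        self.n_random = n_random
        self.n_iter = n_iter
        self.beta = beta
        self.times = times
        self.laplacian_kind = laplacian_kind

    def _evaluate(self, raw: np.ndarray, seed_region: str) -> tuple[float, NDMResults]:
        w = CombinationWeights.from_raw(self.modalities, raw)
        combined = combine_connectomes(self.connectomes, w)
        res = run_pipeline(
            combined, seed_region, None, self.measured,
            self.beta, self.times, self.laplacian_kind,
        )
        return res.sse_opt, res

    def fit(self, rng_seed: int = 0) -> CombinationResults:
        K = len(self.connectomes)
        seeds_rng = child_seeds(rng_seed, len(self.seeds))
        best = None
        per_seed_best: dict[str, float] = {}
        full_trace: list[tuple[str, np.ndarray, float]] = []
        for seed_region, sub_seed in zip(self.seeds, seeds_rng):
            def objective(raw, _seed=seed_region):
                sse, _ = self._evaluate(raw, _seed)
                return sse

            out = gp_minimize(
                objective,
                bounds=[(0.0, 1.0)] * K,
                n_random=self.n_random,
                n_iter=self.n_iter,
                rng=np.random.default_rng(sub_seed),
                x0=list(np.eye(K)),  # every pure modality is in the design
            )
            per_seed_best[seed_region] = out.fun
            full_trace.extend(
                (seed_region, x, f) for x, f in zip(out.x_iters, out.func_vals)
            )
            if best is None or out.fun < best[1]:
                best = (seed_region, out.fun, out.x)
        seed_region, _, raw = best
        weights = CombinationWeights.from_raw(self.modalities, raw)
        _, fit = self._evaluate(raw, seed_region)
        return CombinationResults(
            weights, seed_region, fit, full_trace, rng_seed, per_seed_best
        )


def optimize_weights(
    connectomes: list[Connectome],
    seeds: list[str],
    measured: RegionalPattern,
    n_random: int = 300,
    n_iter: int = 500,
    rng_seed: int = 0,
    **kwargs,
) -> CombinationResults:
    """Functional wrapper around :class:`ConnectomeCombinationModel`."""
    return ConnectomeCombinationModel(
        connectomes, measured, seeds, n_random, n_iter, **kwargs
    ).fit(rng_seed)


@dataclass
class NullEnsembleResult:
    """Observed r_max against a degree-preserving rewired null ensemble."""

    observed_rmax: float
    null_rmax: np.ndarray
    percentile_rank: float  # fraction of nulls strictly below, in percent

    def summary(self) -> str:
        q95 = float(np.percentile(self.null_rmax, 95))
        return (
            f"observed r_max = {self.observed_rmax:.4f}; null ensemble "
            f"n={self.null_rmax.size}, 95th pct = {q95:.4f}; "
            f"observed at percentile {self.percentile_rank:.1f}"
        )


def null_distribution(
    connectome: Connectome,
    measured: RegionalPattern,
    seed_region: str,
    threshold: float | None,
    n_nulls: int = 100,
    rng_seed: int = 0,
    swaps_per_edge: int = 10,
    beta: float = 1.0,
    times: np.ndarray | None = None,
) -> NullEnsembleResult:
    """Benchmark a fit against rewired null connectomes.

    The conditioned, thresholded connectome is rewired ``n_nulls`` times with
    distinct child seeds; every null is fitted with the same seed region, and
    the observed r_max is ranked within the null r_max distribution.
    """
    observed = run_pipeline(connectome, seed_region, threshold, measured, beta, times)
    conditioned = zero_negative_weights(connectome)
    if threshold is not None:
        conditioned = proportional_threshold(conditioned, threshold)
    nulls = np.empty(n_nulls)
    for i, cs in enumerate(child_seeds(rng_seed, n_nulls)):
        null_c = rewire(conditioned, swaps_per_edge, cs)
        nulls[i] = run_pipeline(null_c, seed_region, None, measured, beta, times).r_max
    rank = 100.0 * float(np.mean(nulls < observed.r_max))
    return NullEnsembleResult(observed.r_max, nulls, rank)


def null_combination_test(
    true_connectomes: list[Connectome],
    other_connectomes: list[Connectome],
    measured: RegionalPattern,
    seeds: list[str],
    n_repeats: int = 100,
    rng_seed: int = 0,
    n_random: int = 300,
    n_iter: int = 500,
    swaps_per_edge: int = 10,
    **kwargs,
) -> np.ndarray:
    """Null distribution for the combination: the retained modalities are
    partnered with rewired versions of the other modalities and the weight
    optimisation re-run each repeat.  Returns the best r_max per repeat."""
    if not true_connectomes or not other_connectomes:
        raise ValueError("need at least one true and one other modality")
    out = np.empty(n_repeats)
    for rep, cs in enumerate(child_seeds(rng_seed, n_repeats)):
        sub = child_seeds(cs, len(other_connectomes) + 1)
        partners = [
            rewire(c, swaps_per_edge, s)
            for c, s in zip(other_connectomes, sub[:-1])
        ]
        res = optimize_weights(
            list(true_connectomes) + partners, seeds, measured,
            n_random, n_iter, rng_seed=sub[-1], **kwargs,
        )
        out[rep] = res.fit.r_max
    return out


@dataclass
class CVResult:
    """K-fold cross-validation of unimodal vs combined connectomes."""

    folds: pd.DataFrame  # one row per (fold, model) with train/test r_max
    fold_assignment: np.ndarray
    fold_weights: list[dict]
    fold_selections: list[dict]

    def summary(self) -> str:
        piv = self.folds.pivot_table(
            index="model", values=["train_rmax", "test_rmax"], aggfunc="median"
        )
        return "Cross-validation (median over folds)\n" + piv.to_string()


def cross_validate(
    subject_patterns: list[RegionalPattern],
    connectomes: list[Connectome],
    k: int = 5,
    seeds: list[str] | None = None,
    thresholds: list[float] | None = None,
    rng_seed: int = 0,
    n_random: int = 300,
    n_iter: int = 500,
    beta: float = 1.0,
    times: np.ndarray | None = None,
) -> CVResult:
    """Subject-level k-fold validation of model selection.

    Per fold, the training-subject average pattern drives the unimodal
    seed/threshold grid search and the combined-weight optimisation; the
    frozen selections are then evaluated on the held-out fold average (only
    the model-time scan is re-run on test data).
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    n = len(subject_patterns)
    if n < k:
        raise ValueError("fewer subjects than folds")
    seeds = seeds or ["entorhinal", "fusiform", "inferiortemporal",
                      "middletemporal", "supramarginal"]
    thresholds = thresholds or [0.5, 0.4, 0.3, 0.2, 0.1, 0.05]

    rng = np.random.default_rng(rng_seed)
    assignment = np.arange(n) % k  # balanced: fold sizes differ by <= 1
    rng.shuffle(assignment)
    fold_seeds = child_seeds(rng_seed, k)

    rows, fold_weights, fold_selections = [], [], []
    for fold in range(k):
        train = [p for p, a in zip(subject_patterns, assignment) if a != fold]
        test = [p for p, a in zip(subject_patterns, assignment) if a == fold]
        train_mean = group_average_pattern(train)
        test_mean = group_average_pattern(test)

        selections = {}
        best_uni = None
        for c in connectomes:
            gs = grid_search(c, seeds, thresholds, train_mean, beta, times)
            selections[c.modality] = (gs.best_seed, gs.best_threshold)
            test_fit = run_pipeline(
                c, gs.best_seed, gs.best_threshold, test_mean, beta, times
            )
            rows.append(dict(
                fold=fold, model=c.modality,
                train_rmax=gs.best_fit.r_max, test_rmax=test_fit.r_max,
            ))
            if best_uni is None or gs.best_fit.sse_opt < best_uni[1]:
                best_uni = (c.modality, gs.best_fit.sse_opt,
                            gs.best_fit.r_max, test_fit.r_max)

        pre = [
            proportional_threshold(
                zero_negative_weights(c), selections[c.modality][1]
            )
            for c in connectomes
        ]
        comb = optimize_weights(
            pre, seeds, train_mean, n_random, n_iter,
            rng_seed=fold_seeds[fold], beta=beta, times=times,
        )
        comb_pre = [
            proportional_threshold(
                zero_negative_weights(c), selections[c.modality][1]
            ) for c in connectomes
        ]
        combined_c = combine_connectomes(comb_pre, comb.weights)
        comb_test = run_pipeline(
            combined_c, comb.seed_region, None, test_mean, beta, times
        )
        rows.append(dict(
            fold=fold, model="combined",
            train_rmax=comb.fit.r_max, test_rmax=comb_test.r_max,
        ))
        rows.append(dict(
            fold=fold, model="best_unimodal",
            train_rmax=best_uni[2], test_rmax=best_uni[3],
        ))
        fold_weights.append(dict(comb.weights.lambdas))
        fold_selections.append(selections)

    return CVResult(pd.DataFrame(rows), assignment, fold_weights, fold_selections)


@dataclass
class StabilityResult:
    """r_max spread over repeated subject-subsample connectome averages."""

    rmax: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.rmax.mean())

    @property
    def sd(self) -> float:
        if self.rmax.size < 2 or np.ptp(self.rmax) == 0:
            return 0.0
        return float(self.rmax.std(ddof=1))


def stability_analysis(
    subject_connectomes: list[Connectome],
    measured: RegionalPattern,
    seed_region: str,
    threshold: float | None,
    n_subsample: int = 30,
    n_repeats: int = 100,
    rng_seed: int = 0,
    beta: float = 1.0,
    times: np.ndarray | None = None,
) -> StabilityResult:
    """Sample ``n_subsample`` subjects without replacement, average their
    connectomes, fit the model; repeat to measure r_max stability."""
    if n_subsample > len(subject_connectomes):
        raise ValueError("subsample larger than the cohort")
    rng = np.random.default_rng(rng_seed)
    rmax = np.empty(n_repeats)
    for i in range(n_repeats):
        pick = rng.choice(len(subject_connectomes), n_subsample, replace=False)
        avg = group_average([subject_connectomes[j] for j in pick])
        rmax[i] = run_pipeline(
            avg, seed_region, threshold, measured, beta, times
        ).r_max
    return StabilityResult(rmax)
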