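"""Synthetic study fixtures.

Generates modality-styled connectomes with a controllable shared latent
backbone, forward-simulated pathology patterns from a known seed, model time
and combination weights, subject cohorts of noisy connectomes and patterns,
and cortical-thickness tables with planted covariance blocks — everything the
fitting machinery consumes, with no external data.

The default world uses the 68 real Desikan-Killiany cortical labels (an
86-node variant appends 18 subcortical labels), four modalities sharing 30%
of their edge structure, true weights (0.6, 0.2, 0.15, 0.05), a bilateral
inferior-temporal seed, a mid-trajectory generating time (the pattern has
spread over the cortex — median burden about a third of the peak — but has
not equilibrated), and additive Gaussian observation noise of sd 0.02.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectome import (
    CombinationWeights,
    Connectome,
    combine_connectomes,
    proportional_threshold,
    write_connectome,
    zero_negative_weights,
)
from .covariance import SubjectMeasureTable
from .diffusion import graph_laplacian, make_seed, simulate
from .labels import cortical_labels_68, labels_86
from .pathology import RegionalPattern, subset_cortical

STYLES = ("distance", "modular", "dense-covariance")


def _mirrored_coordinates(labels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Random 3-D node coordinates with left/right mirror symmetry."""
    n = len(labels)
    half = n // 2
    coords = np.empty((n, 3))
    lh = rng.uniform([0.0, 0.0, 0.0], [0.45, 1.0, 1.0], size=(half, 3))
    coords[:half] = lh
    coords[half:] = lh * [-1.0, 1.0, 1.0] + [1.0, 0.0, 0.0]  # mirror in x
    return coords


def _condition(w: np.ndarray, labels: list[str], modality: str) -> Connectome:
    w = np.clip((w + w.T) / 2.0, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return Connectome(w, labels, modality)


def synth_connectome(
    n_regions: int = 68,
    style: str = "distance",
    rng_seed: int | np.random.Generator = 0,
    labels: list[str] | None = None,
    length_scale: float = 0.25,
    n_blocks: int = 4,
    n_factors: int = 5,
) -> Connectome:
    """One synthetic connectome in a given modality style.

    ``distance``: weights decay exponentially with Euclidean distance between
    mirror-symmetric random 3-D coordinates, with multiplicative lognormal
    noise (emulates tractography / inverse-geodesic networks).
    ``modular``: planted block structure with strong within-block weights.
    ``dense-covariance``: correlation matrix of a latent-factor model
    (emulates morphological / microstructural covariance networks).
    """
    if n_regions < 6 or n_regions % 2:
        raise ValueError("n_regions must be even and >= 6")
    rng = np.random.default_rng(rng_seed)
    labels = labels or _default_labels(n_regions)

    if style == "distance":
        coords = _mirrored_coordinates(labels, rng)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        w = np.exp(-d / length_scale)
        noise = np.exp(rng.normal(0.0, 0.3, size=d.shape))
        w = w * (noise + noise.T) / 2.0
    elif style == "modular":
        blocks = rng.integers(0, n_blocks, size=n_regions)
        same = blocks[:, None] == blocks[None, :]
        w = np.where(
            same,
            np.abs(rng.normal(1.0, 0.2, size=(n_regions, n_regions))),
            np.abs(rng.normal(0.15, 0.05, size=(n_regions, n_regions))),
        )
    elif style == "dense-covariance":
        load = rng.normal(0.0, 1.0, size=(n_regions, n_factors))
        cov = load @ load.T + 0.5 * np.eye(n_regions)
        d = np.sqrt(np.diag(cov))
        w = cov / np.outer(d, d)
    else:
        raise ValueError(f"unknown style {style!r}; pick one of {STYLES}")
    return _condition(w, labels, style)


def _default_labels(n_regions: int) -> list[str]:
    if n_regions == 68:
        return cortical_labels_68()
    if n_regions == 86:
        return labels_86()
    half = n_regions // 2
    return [f"lh_region{i:03d}" for i in range(half)] + [
        f"rh_region{i:03d}" for i in range(half)
    ]


def synth_multimodal(
    n_regions: int = 68,
    K: int = 4,
    shared_fraction: float = 0.3,
    rng_seed: int = 0,
    labels: list[str] | None = None,
) -> list[Connectome]:
    """K modality connectomes sharing a latent backbone.

    Every modality is ``shared_fraction`` x backbone + (1 - shared_fraction)
    x an independent modality-specific network, each component scaled to unit
    mean edge weight first, so pairwise edge-weight correlation between
    modalities rises monotonically with ``shared_fraction``.
    """
    if K < 2:
        raise ValueError("need K >= 2 modalities")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    labels = labels or _default_labels(n_regions)
    styles = [STYLES[i % len(STYLES)] for i in range(K)]

    def unit_mean(c: Connectome) -> np.ndarray:
        m = c.weights[c.weights > 0].mean()
        return c.weights / m

    backbone = unit_mean(synth_connectome(n_regions, "distance", rng, labels))
    out = []
    for k, style in enumerate(styles):
        own = unit_mean(synth_connectome(n_regions, style, rng, labels))
        w = shared_fraction * backbone + (1.0 - shared_fraction) * own
        out.append(_condition(w, labels, f"mod{k}_{style}"))
    return out


@dataclass
class SyntheticWorld:
    """A complete synthetic study: connectomes, generating parameters, truth."""

    connectomes: list[Connectome]
    true_weights: CombinationWeights
    seed_region: str
    t_star: float
    threshold: float
    noise_sd: float
    rng_seed: int
    region_labels: list[str] = field(default_factory=list)

    @classmethod
    def default(
        cls,
        n_regions: int = 68,
        K: int = 4,
        shared_fraction: float = 0.3,
        true_weights: tuple = (0.6, 0.2, 0.15, 0.05),
        seed_region: str = "inferiortemporal",
        t_star: float = 10.0,
        threshold: float = 0.3,
        noise_sd: float = 0.02,
        rng_seed: int = 0,
    ) -> "SyntheticWorld":
        conns = synth_multimodal(n_regions, K, shared_fraction, rng_seed)
        lam = CombinationWeights.from_raw(
            [c.modality for c in conns], np.asarray(true_weights, float)
        )
        return cls(
            conns, lam, seed_region, t_star, threshold, noise_sd, rng_seed,
            list(conns[0].region_labels),
        )

    def combined(self) -> Connectome:
        pre = [
            proportional_threshold(zero_negative_weights(c), self.threshold)
            for c in self.connectomes
        ]
        return combine_connectomes(pre, self.true_weights)

    def thresholded(self) -> list[Connectome]:
        return [
            proportional_threshold(zero_negative_weights(c), self.threshold)
            for c in self.connectomes
        ]


def noiseless_pattern(
    world: SyntheticWorld,
    connectome: Connectome | None = None,
    beta: float = 1.0,
) -> RegionalPattern:
    """Forward-model pattern at the world's true seed and time, no noise."""
    c = connectome if connectome is not None else world.combined()
    op = graph_laplacian(zero_negative_weights(c), beta)
    x0 = make_seed(op.region_labels, world.seed_region)
    traj = simulate(op, x0, np.array([world.t_star]))
    full = RegionalPattern(
        np.clip(traj.raw_states[0], 0.0, None) / max(traj.raw_states[0].max(), 1e-30),
        op.region_labels,
        "simulated",
    )
    cortical = subset_cortical(full)
    v = cortical.values
    span = v.max() - v.min()
    if span < 1e-12:
        raise ValueError("degenerate forward pattern; pick a smaller t_star")
    return RegionalPattern((v - v.min()) / span, cortical.region_labels, "simulated")


def synth_pathology(
    world: SyntheticWorld,
    rng_seed: int | None = None,
    n_subjects: int | None = None,
    subject_noise_sd: float | None = None,
) -> RegionalPattern | list[RegionalPattern]:
    """Observed pathology: forward pattern plus Gaussian noise, clipped to [0,1].

    With ``n_subjects`` set, returns a cohort of per-subject patterns drawn
    around the group pattern with ``subject_noise_sd`` (defaults to the
    world's noise sd).
    """
    rng = np.random.default_rng(world.rng_seed if rng_seed is None else rng_seed)
    clean = noiseless_pattern(world)
    if n_subjects is None:
        noisy = clean.values + rng.normal(0.0, world.noise_sd, clean.values.size)
        return RegionalPattern(
            np.clip(noisy, 0.0, 1.0), clean.region_labels, "simulated"
        )
    sd = world.noise_sd if subject_noise_sd is None else subject_noise_sd
    return [
        RegionalPattern(
            np.clip(
                clean.values + rng.normal(0.0, sd, clean.values.size), 0.0, 1.0
            ),
            clean.region_labels,
            "simulated",
        )
        for _ in range(n_subjects)
    ]


def synth_subject_connectomes(
    truth: Connectome, n_subjects: int, noise_sd: float, rng_seed: int = 0
) -> list[Connectome]:
    """Subject-level connectomes: truth plus i.i.d. edgewise Gaussian noise."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_subjects):
        eps = rng.normal(0.0, noise_sd, size=truth.weights.shape)
        out.append(_condition(truth.weights + eps, truth.region_labels,
                              truth.modality))
    return out


def synth_thickness_table(
    n_subjects: int = 100,
    n_regions: int = 68,
    n_blocks: int = 2,
    factor_sd: float = 0.15,
    age_slope: float = -0.01,
    sex_offset: float = 0.05,
    noise_sd: float = 0.05,
    rng_seed: int = 0,
    labels: list[str] | None = None,
) -> SubjectMeasureTable:
    """Cortical-thickness table with planted block covariance.

    thickness = baseline + age slope + sex offset + shared block factor
    + noise; the block factors make within-block regions covary across
    subjects, recoverable by the morphological-covariance network.
    """
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    rng = np.random.default_rng(rng_seed)
    labels = labels or _default_labels(n_regions)
    age = rng.uniform(55.0, 90.0, n_subjects)
    sex = rng.integers(0, 2, n_subjects).astype(float)
    blocks = np.arange(n_regions) % max(n_blocks, 1)
    factors = rng.normal(0.0, factor_sd, size=(n_subjects, max(n_blocks, 1)))
    baseline = rng.uniform(2.2, 3.0, n_regions)
    values = (
        baseline[None, :]
        + age_slope * (age[:, None] - 70.0)
        + sex_offset * sex[:, None]
        + factors[:, blocks]
        + rng.normal(0.0, noise_sd, size=(n_subjects, n_regions))
    )
    return SubjectMeasureTable(values, labels, age, sex)


def write_fixture_dir(world: SyntheticWorld, path, n_subjects: int = 40,
                      rng_seed: int | None = None) -> Path:
    """Write a complete fixture directory: per-modality connectome CSVs, a
    group pathology pattern, a subject cohort, a thickness table and a
    manifest recording the generating truth."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for c in world.connectomes:
        write_connectome(c, path / f"connectome_{c.modality}.csv")
    pattern = synth_pathology(world)
    pattern.to_csv(path / "pathology_group.csv")
    cohort = synth_pathology(world, n_subjects=n_subjects,
                             rng_seed=rng_seed)
    import pandas as pd

    rows = {f"subject_{i:03d}": p.values for i, p in enumerate(cohort)}
    pd.DataFrame(rows, index=cohort[0].region_labels).T.rename_axis(
        "subject"
    ).to_csv(path / "pathology_subjects.csv")
    table = synth_thickness_table(
        max(n_subjects, 10), len(world.region_labels),
        rng_seed=world.rng_seed, labels=world.region_labels,
    )
    table.to_csv(path / "thickness.csv")
    manifest = {
        "true_weights": {k: float(v) for k, v in world.true_weights.lambdas.items()},
        "seed_region": world.seed_region,
        "t_star": world.t_star,
        "threshold": world.threshold,
        "noise_sd": world.noise_sd,
        "rng_seed": world.rng_seed,
        "modalities": [c.modality for c in world.connectomes],
        "n_regions": len(world.region_labels),
    }
    (path / "world.json").write_text(json.dumps(manifest, indent=2))
    return path
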