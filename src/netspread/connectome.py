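"""Connectome container, CSV I/O and graph-conditioning operations.

A connectome is a symmetric, non-negative, zero-diagonal weighted adjacency
matrix over labelled brain regions.  The conditioning pipeline applied before
diffusion modelling is: zero negative weights -> proportional threshold ->
row-normalise -> graph Laplacian.  Degree-preserving rewiring provides the
null networks used to benchmark model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import is_cortical

_SYM_RTOL = 1e-10


@dataclass
class Connectome:
    """Labelled, symmetric, weighted connectivity matrix.

    Parameters
    ----------
    weights : ndarray of shape (n, n)
        Symmetric non-negative connectivity estimates; zero diagonal.
    region_labels : list of str
        Unique region names, ``lh_``/``rh_`` prefixed for cortex.
    modality : str
        Free-form tag, e.g. ``"tractography"`` or ``"combined"``.
    """

    weights: np.ndarray
    region_labels: list[str]
    modality: str = "unknown"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] != len(self.region_labels):
            raise ValueError(
                f"{w.shape[0]} rows but {len(self.region_labels)} region labels"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise ValueError(f"non-finite weight at ({i}, {j})")
        scale = max(float(np.abs(w).max()), 1.0)
        if not np.allclose(w, w.T, atol=_SYM_RTOL * scale, rtol=0.0):
            raise ValueError("weights matrix is not symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.region_labels = list(self.region_labels)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_edges(self) -> int:
        """Number of nonzero upper-triangle edges."""
        iu = np.triu_indices(self.n_regions, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def cortical_mask(self) -> np.ndarray:
        return np.array([is_cortical(l) for l in self.region_labels])

    def with_weights(self, weights: np.ndarray, modality: str | None = None) -> "Connectome":
        return Connectome(weights, self.region_labels, modality or self.modality)

    # conveniences delegating to module functions
    def zero_negative(self) -> "Connectome":
        return zero_negative_weights(self)

    def threshold(self, fraction: float) -> "Connectome":
        return proportional_threshold(self, fraction)


@dataclass
class CombinationWeights:
    """Simplex-constrained modality weights for connectome combination."""

    lambdas: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.lambdas.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("combination weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {vals.sum():.12f}")

    @classmethod
    def from_raw(cls, modalities: list[str], raw: np.ndarray) -> "CombinationWeights":
        """Normalise a raw non-negative vector onto the simplex.

        An (effectively) all-zero vector maps to uniform weights.
        """
        raw = np.clip(np.asarray(raw, dtype=float), 0.0, None)
        s = raw.sum()
        if s < 1e-12:
            raw = np.ones_like(raw)
            s = raw.sum()
        return cls(dict(zip(modalities, raw / s)))

    def as_array(self, modalities: list[str]) -> np.ndarray:
        return np.array([self.lambdas[m] for m in modalities], dtype=float)


def read_connectome(path, tag: str = "unknown") -> Connectome:
    """Read a labelled CSV connectivity matrix.

    The first row and first column must carry identical region labels.
    Asymmetric entries are symmetrised by averaging; the diagonal is zeroed.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        bad = next(i for i, (r, c) in enumerate(zip(rows, cols)) if r != c)
        raise ValueError(
            f"{path}: row/column label mismatch at position {bad}: "
            f"{rows[bad]!r} vs {cols[bad]!r}"
        )
    w = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ValueError(
            f"{path}: non-finite entry at row {rows[i]!r}, column {cols[j]!r}"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return Connectome(w, rows, tag)


def write_connectome(c: Connectome, path) -> None:
    pd.DataFrame(c.weights, index=c.region_labels, columns=c.region_labels).to_csv(path)


def zero_negative_weights(c: Connectome) -> Connectome:
    return c.with_weights(np.clip(c.weights, 0.0, None))


def proportional_threshold(c: Connectome, fraction: float) -> Connectome:
    """Retain the strongest ``fraction`` of existing edges, zero the rest.

    ``k = ceil(fraction * E)`` edges are kept among the E nonzero
    upper-triangle edges; ties at the cut weight resolve in ascending
    (row, column) order.  Retained weights are unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"threshold fraction must be in (0, 1], got {fraction}")
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = c.weights[iu, ju]
    nz = np.nonzero(w)[0]
    if nz.size == 0:
        return c.with_weights(c.weights.copy())
    k = math.ceil(fraction * nz.size)
    # stable sort on (-weight, row, col): lexsort keys in reverse priority
    order = np.lexsort((ju[nz], iu[nz], -w[nz]))
    keep = nz[order[:k]]
    out = np.zeros_like(c.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return c.with_weights(out)


def row_normalize(c: Connectome) -> np.ndarray:
    """Row-stochastic adjacency: each positive row divided by its sum.

    All-zero rows (isolated nodes) remain zero.  The result is generally
    asymmetric and returned as a plain array.
    """
    w = np.clip(c.weights, 0.0, None)
    rowsum = w.sum(axis=1)
    out = np.zeros_like(w)
    pos = rowsum > 0
    out[pos] = w[pos] / rowsum[pos, None]
    return out


def combine_connectomes(
    connectomes: list[Connectome],
    weights: CombinationWeights,
    align: str = "intersection",
) -> Connectome:
    """Entrywise convex combination of single-modality connectomes.

    Regions are aligned by label.  With ``align='intersection'`` (default)
    regions absent from any modality are dropped; ``align='union'`` zero-pads
    missing regions instead.
    """
    if align not in ("intersection", "union"):
        raise ValueError(f"unknown align mode {align!r}")
    mods = [c.modality for c in connectomes]
    if len(set(mods)) != len(mods):
        raise ValueError("modality tags must be unique for combination")
    lam = weights.as_array(mods)

    if align == "intersection":
        common = set(connectomes[0].region_labels)
        for c in connectomes[1:]:
            common &= set(c.region_labels)
        if not common:
            raise ValueError("empty region-label intersection")
        labels = [l for l in connectomes[0].region_labels if l in common]
    else:
        labels = list(connectomes[0].region_labels)
        seen = set(labels)
        for c in connectomes[1:]:
            for l in c.region_labels:
                if l not in seen:
                    labels.append(l)
                    seen.add(l)

    n = len(labels)
    out = np.zeros((n, n))
    for lam_k, c in zip(lam, connectomes):
        idx = {l: i for i, l in enumerate(c.region_labels)}
        present = [i for i, l in enumerate(labels) if l in idx]
        src = np.array([idx[labels[i]] for i in present], dtype=int)
        dst = np.array(present, dtype=int)
        out[np.ix_(dst, dst)] += lam_k * c.weights[np.ix_(src, src)]
    return Connectome(out, labels, "combined")


def rewire(c: Connectome, swaps_per_edge: int = 10, rng_seed: int | None = 0) -> Connectome:
    """Degree-preserving randomisation by weighted double-edge swaps.

    Pairs of edges (A-B, C-D) are repeatedly swapped to (A-D, C-B), with each
    weight travelling with its edge; swaps creating self-loops or duplicate
    edges are rejected.  ``swaps_per_edge * E`` swaps are attempted, so each
    edge is rewired approximately ``swaps_per_edge`` times.  The binary degree
    sequence and the multiset of edge weights are preserved exactly.
    """
    rng = np.random.default_rng(rng_seed)
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    mask = c.weights[iu, ju] != 0
    edges = [[int(a), int(b), float(w)] for a, b, w in
             zip(iu[mask], ju[mask], c.weights[iu, ju][mask])]
    E = len(edges)
    if E < 2:
        raise ValueError("rewiring needs at least 2 edges")
    adjacency = {(e[0], e[1]) for e in edges}

    def has(a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in adjacency

    attempts = swaps_per_edge * E
    pairs = rng.integers(0, E, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for (e1, e2), flip in zip(pairs, flips):
        if e1 == e2:
            continue
        a, b, w1 = edges[e1]
        c0, d0, w2 = edges[e2]
        cc, d = (d0, c0) if flip else (c0, d0)
        # proposed new edges a-d and cc-b
        if a == d or cc == b:
            continue
        if has(a, d) or has(cc, b):
            continue
        adjacency.discard((a, b))
        adjacency.discard((c0, d0))
        adjacency.add((min(a, d), max(a, d)))
        adjacency.add((min(cc, b), max(cc, b)))
        edges[e1] = [min(a, d), max(a, d), w1]
        edges[e2] = [min(cc, b), max(cc, b), w2]
    out = np.zeros_like(c.weights)
    for a, b, w in edges:
        out[a, b] = w
        out[b, a] = w
    return c.with_weights(out)


def group_average(connectomes: list[Connectome]) -> Connectome:
    """Entrywise arithmetic mean of same-labelled connectomes."""
    ref = connectomes[0]
    for c in connectomes[1:]:
        if c.region_labels != ref.region_labels:
            raise ValueError("region labels differ across subjects")
        if c.modality != ref.modality:
            raise ValueError("modality tags differ across subjects")
    mean = np.mean([c.weights for c in connectomes], axis=0)
    return ref.with_weights(mean)
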