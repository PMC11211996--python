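"""Connectome container, I/O, conditioning, combination and rewiring."""

import math

import numpy as np
import pytest

from netspread import (
    CombinationWeights,
    Connectome,
    combine_connectomes,
    group_average,
    proportional_threshold,
    read_connectome,
    rewire,
    row_normalize,
    write_connectome,
    zero_negative_weights,
)

from conftest import random_connected_connectome

L3 = ["lh_a", "rh_a", "lh_b"]


def _c(w, labels=None, tag="t"):
    return Connectome(np.asarray(w, float), labels or L3[: len(w)], tag)


class TestReadWrite:
    def test_read_labelled_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(",lh_a,rh_a,lh_b\nlh_a,0,1,2\nrh_a,1,0,3\nlh_b,2,3,0\n")
        c = read_connectome(p, "tracto")
        assert c.n_regions == 3 and c.n_edges == 3
        assert c.modality == "tracto"
        assert c.weights[0, 1] == 1 and c.weights[1, 2] == 3

    def test_asymmetric_pair_averaged(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(",lh_a,rh_a\nlh_a,0,1.0\nrh_a,1.2,0\n")
        c = read_connectome(p)
        assert c.weights[0, 1] == pytest.approx(1.1)
        assert c.weights[1, 0] == pytest.approx(1.1)

    def test_nan_entry_rejected_with_cell(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(",lh_a,rh_a\nlh_a,0,nan\nrh_a,1,0\n")
        with pytest.raises(ValueError, match="lh_a.*rh_a|rh_a.*lh_a"):
            read_connectome(p)

    def test_label_mismatch_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(",lh_a,rh_a\nlh_a,0,1\nlh_b,1,0\n")
        with pytest.raises(ValueError, match="mismatch"):
            read_connectome(p)

    def test_round_trip(self, tmp_path, small_connectome):
        p = tmp_path / "c.csv"
        write_connectome(small_connectome, p)
        back = read_connectome(p, small_connectome.modality)
        np.testing.assert_allclose(back.weights, small_connectome.weights,
                                   rtol=1e-12, atol=1e-15)
        assert back.region_labels == small_connectome.region_labels


class TestConditioning:
    def test_zero_negative(self):
        c = Connectome(np.array([[0, -0.3], [-0.3, 0.0]]), ["lh_a", "rh_a"])
        out = zero_negative_weights(c)
        assert np.all(out.weights == 0)

    def test_zero_negative_identity_on_positive(self, small_connectome):
        out = zero_negative_weights(small_connectome)
        np.testing.assert_array_equal(out.weights, small_connectome.weights)

    def test_zero_negative_mixed(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = -1.0
        w[2, 3] = w[3, 2] = -0.5
        w[0, 2] = w[2, 0] = 2.0
        labels = ["lh_a", "rh_a", "lh_b", "rh_b"]
        out = zero_negative_weights(Connectome(w, labels))
        assert out.weights[0, 1] == 0 and out.weights[2, 3] == 0
        assert out.weights[0, 2] == 2.0

    def test_threshold_retains_strongest(self):
        w = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        c = Connectome(w, ["lh_a", "rh_a", "lh_b", "rh_b"])
        out = proportional_threshold(c, 0.5)
        kept = sorted(out.weights[np.triu_indices(4, 1)][
            out.weights[np.triu_indices(4, 1)] > 0])
        assert kept == [0.7, 0.8, 0.9]

    def test_threshold_one_is_identity(self, small_connectome):
        out = proportional_threshold(small_connectome, 1.0)
        np.testing.assert_array_equal(out.weights, small_connectome.weights)

    def test_threshold_count_matches_sort_oracle(self, rng):
        c = random_connected_connectome(100, rng)
        frac = 0.05
        out = proportional_threshold(c, frac)
        iu = np.triu_indices(100, 1)
        E = int(np.count_nonzero(c.weights[iu]))
        k = math.ceil(frac * E)
        assert int(np.count_nonzero(out.weights[iu])) == k
        # brute force: the retained edges are exactly the k largest weights
        top = np.sort(c.weights[iu][c.weights[iu] > 0])[-k:]
        kept = np.sort(out.weights[iu][out.weights[iu] > 0])
        np.testing.assert_allclose(kept, top)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_rejects_bad_fraction(self, small_connectome, bad):
        with pytest.raises(ValueError):
            proportional_threshold(small_connectome, bad)

    def test_threshold_monotone_edge_subset(self, rng):
        c = random_connected_connectome(30, rng)
        e1 = proportional_threshold(c, 0.2).weights > 0
        e2 = proportional_threshold(c, 0.6).weights > 0
        assert np.all(e2 | ~e1)  # edges at 0.2 are a subset of edges at 0.6

    def test_row_normalize(self):
        c = _c([[0, 2], [2, 0]], ["lh_a", "rh_a"])
        np.testing.assert_array_equal(row_normalize(c), [[0, 1], [1, 0]])

    def test_row_normalize_isolated_row_stays_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        P = row_normalize(Connectome(w, L3))
        assert np.all(P[2] == 0)

    def test_row_normalize_rows_sum_to_one(self, rng):
        c = random_connected_connectome(5, rng)
        P = row_normalize(c)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestValidation:
    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            Connectome(np.zeros((2, 3)), ["lh_a", "rh_a"])

    def test_asymmetric_rejected(self):
        w = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            Connectome(w, ["lh_a", "rh_a"])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Connectome(np.zeros((2, 2)), ["lh_a", "lh_a"])


class TestCombination:
    def test_one_hot_recovers_single_modality(self, world):
        conns = world.thresholded()
        mods = [c.modality for c in conns]
        w = CombinationWeights.from_raw(mods, np.eye(len(mods))[0])
        out = combine_connectomes(conns, w)
        np.testing.assert_allclose(out.weights, conns[0].weights, atol=1e-15)
        assert out.modality == "combined"

    def test_convexity_of_identical_inputs(self, small_connectome):
        a = small_connectome
        b = a.with_weights(a.weights.copy(), "other")
        w = CombinationWeights({a.modality: 0.3, "other": 0.7})
        out = combine_connectomes([a, b], w)
        np.testing.assert_allclose(out.weights, a.weights, rtol=1e-12)

    def test_reported_optimal_weight_vector_is_valid(self):
        # the tau-optimal configuration over four modalities sums to one
        w = CombinationWeights({
            "tractography": 0.61, "morphological": 0.14,
            "inverse-geodesic": 0.20, "microstructural": 0.05,
        })
        assert sum(w.lambdas.values()) == pytest.approx(1.0)

    def test_linearity_in_weights(self, world):
        conns = world.thresholded()
        mods = [c.modality for c in conns]
        w1 = np.array([0.7, 0.1, 0.1, 0.1])
        w2 = np.array([0.1, 0.3, 0.3, 0.3])
        alpha = 0.25
        mix = CombinationWeights.from_raw(mods, alpha * w1 + (1 - alpha) * w2)
        a = combine_connectomes(conns, CombinationWeights.from_raw(mods, w1))
        b = combine_connectomes(conns, CombinationWeights.from_raw(mods, w2))
        out = combine_connectomes(conns, mix)
        np.testing.assert_allclose(
            out.weights, alpha * a.weights + (1 - alpha) * b.weights, atol=1e-12
        )

    def test_intersection_alignment_drops_missing_regions(self, world):
        conns = world.thresholded()
        shorter = Connectome(
            conns[1].weights[:-2, :-2], conns[1].region_labels[:-2], "short"
        )
        mods = [conns[0].modality, "short"]
        out = combine_connectomes(
            [conns[0], shorter], CombinationWeights.from_raw(mods, np.ones(2))
        )
        assert out.region_labels == conns[0].region_labels[:-2]

    def test_disjoint_labels_rejected(self):
        a = _c([[0, 1], [1, 0]], ["lh_a", "rh_a"], "m1")
        b = _c([[0, 1], [1, 0]], ["lh_b", "rh_b"], "m2")
        with pytest.raises(ValueError, match="intersection"):
            combine_connectomes(
                [a, b], CombinationWeights({"m1": 0.5, "m2": 0.5})
            )


class TestRewire:
    def test_invariants_preserved(self, rng):
        c = random_connected_connectome(40, rng)
        iu = np.triu_indices(40, 1)
        for seed in (0, 1, 2):
            r = rewire(c, 10, seed)
            np.testing.assert_array_equal(
                (r.weights > 0).sum(0), (c.weights > 0).sum(0)
            )
            np.testing.assert_allclose(
                np.sort(r.weights[iu][r.weights[iu] > 0]),
                np.sort(c.weights[iu][c.weights[iu] > 0]),
            )

    def test_deterministic_given_seed(self, rng):
        c = random_connected_connectome(30, rng)
        np.testing.assert_array_equal(
            rewire(c, 10, 99).weights, rewire(c, 10, 99).weights
        )

    def test_randomises_edge_placement(self, rng):
        c = random_connected_connectome(25, rng, density=0.4)
        iu = np.triu_indices(25, 1)
        orig = c.weights[iu] > 0
        assert orig.sum() >= 100
        shared = [
            (orig & (rewire(c, 10, s).weights[iu] > 0)).sum() / orig.sum()
            for s in range(20)
        ]
        assert np.mean(shared) < 0.5

    def test_too_few_edges_rejected(self):
        c = _c([[0, 1], [1, 0]], ["lh_a", "rh_a"])
        with pytest.raises(ValueError):
            rewire(c, 10, 0)


class TestGroupAverage:
    def test_identity(self, small_connectome):
        out = group_average([small_connectome, small_connectome])
        np.testing.assert_array_equal(out.weights, small_connectome.weights)

    def test_arithmetic(self):
        a = _c([[0, 1], [1, 0]], ["lh_a", "rh_a"])
        b = _c([[0, 3], [3, 0]], ["lh_a", "rh_a"])
        np.testing.assert_array_equal(
            group_average([a, b]).weights, [[0, 2], [2, 0]]
        )

    def test_matches_accumulation_oracle(self, rng):
        subs = [random_connected_connectome(12, rng) for _ in range(50)]
        subs = [s.with_weights(s.weights, "m") for s in subs]
        out = group_average(subs)
        acc = np.zeros((12, 12))
        for s in subs:
            acc += s.weights
        np.testing.assert_allclose(out.weights, acc / 50, atol=1e-12)

    def test_label_mismatch_rejected(self):
        a = _c([[0, 1], [1, 0]], ["lh_a", "rh_a"])
        b = _c([[0, 1], [1, 0]], ["lh_b", "rh_b"])
        with pytest.raises(ValueError):
            group_average([a, b])
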