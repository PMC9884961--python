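"""Closed-form values, oracles and gradient checks for all loss terms."""

import math

import numpy as np
import pytest

from retinakey.autodiff import Tensor
from retinakey.losses import (PairSets, build_pair_sets, cross_entropy_loss,
                              dice_loss, euclidean_distance,
                              keypoint_target_mask, matching_loss,
                              pairwise_ranking_loss, sample_embeddings_at,
                              structured_triplet_loss, total_loss,
                              triplet_ranking_loss)

from conftest import finite_difference_grad


def structured_loss_by_double_loop(Ef, Em, pair_sets):
    """Naive evaluation of the structured triplet ranking loss."""
    m = pair_sets.margin
    d = lambda a, b: np.sqrt(((a - b) ** 2).sum() + 1e-16)
    total = 0.0
    for (i, j) in pair_sets.positives:
        inner = 0.0
        for (a, p) in pair_sets.negatives_fixed:
            if a == i:
                inner += math.exp(m - d(Ef[i], Em[p]))
        for (a, l) in pair_sets.negatives_moving:
            if a == j:
                inner += math.exp(m - d(Em[j], Ef[l]))
        term = d(Ef[i], Em[j]) + (math.log(inner) if inner > 0 else 0.0)
        total += max(term, 0.0)
    return total / (2 * len(pair_sets.positives))


class TestTargetMask:
    def test_empty_keypoints_all_zero(self):
        mask = keypoint_target_mask(np.zeros((0, 2)), (8, 8), 2)
        assert mask.sum() == 0

    def test_radius_zero_single_pixel(self):
        mask = keypoint_target_mask([[3.4, 5.6]], (10, 10), 0)
        assert mask.sum() == 1
        assert mask[6, 3] == 1  # (x, y) -> (row, col)

    def test_count_matches_per_pixel_distance_oracle(self):
        pts = [[10.3, 7.8], [20.0, 25.5]]
        radius = 2.0
        mask = keypoint_target_mask(pts, (32, 32), radius)
        count = 0
        for r in range(32):
            for c in range(32):
                if any((c - x) ** 2 + (r - y) ** 2 <= radius ** 2 for x, y in pts):
                    count += 1
        assert mask.sum() == count


class TestLocationLosses:
    def test_cross_entropy_closed_forms(self):
        one = np.ones((1, 1))
        half = np.full((1, 1), 0.5)
        assert cross_entropy_loss(one, one).item() == pytest.approx(0.0, abs=1e-6)
        assert cross_entropy_loss(half, one).item() == pytest.approx(math.log(2), abs=1e-6)
        assert cross_entropy_loss(half, np.zeros((1, 1))).item() == pytest.approx(
            math.log(2), abs=1e-6)

    def test_cross_entropy_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_dice_closed_forms(self):
        a = np.zeros((4, 4))
        a[:2] = 1
        assert dice_loss(a, a, smooth=0).item() == pytest.approx(0.0, abs=1e-6)
        b = np.zeros((4, 4))
        b[2:] = 1
        assert dice_loss(a, b, smooth=0).item() == pytest.approx(1.0, abs=1e-6)
        p = np.zeros((4, 4))
        y = np.zeros((4, 4))
        p[0, :2] = 1
        y[0, 1:3] = 1  # |P|=|Y|=2, one shared pixel
        assert dice_loss(p, y, smooth=0).item() == pytest.approx(0.5, abs=1e-6)


class TestRankingLosses:
    def test_pairwise_closed_forms(self):
        f = np.array([1.0, 2.0, 3.0])
        m = 1.0
        assert pairwise_ranking_loss(f, f, True, m).item() == pytest.approx(0.0, abs=1e-6)
        far = f + np.array([2 * m, 0, 0])
        assert pairwise_ranking_loss(f, far, False, m).item() == 0.0
        assert pairwise_ranking_loss(f, f, False, m).item() == pytest.approx(m, abs=1e-6)

    def test_triplet_closed_forms(self):
        a = np.zeros(4)
        m = 1.0
        n_at_margin = np.array([m, 0, 0, 0])
        assert triplet_ranking_loss(a, a, n_at_margin, m).item() == pytest.approx(
            0.0, abs=1e-6)
        x = np.array([0.7, 0, 0, 0])
        assert triplet_ranking_loss(a, x, x, m).item() == pytest.approx(m, abs=1e-9)
        p = np.array([0.5, 0, 0, 0])
        n = np.array([0.2, 0, 0, 0])
        assert triplet_ranking_loss(a, p, n, 1.0).item() == pytest.approx(1.3, abs=1e-6)

    def test_structured_one_positive_two_negatives_closed_form(self):
        m = 1.0
        # one positive (0, 0) at distance 0; one negative for each anchor at
        # distance exactly m -> (1/2) * [0 + log(e^0 + e^0)]_+ = ln(2) / 2
        Ef = Tensor(np.array([[0.0, 0.0], [m, 0.0]]))
        Em = Tensor(np.array([[0.0, 0.0], [m, 0.0]]))
        ps = PairSets(positives=[(0, 0)], negatives_fixed=[(0, 1)],
                      negatives_moving=[(0, 1)], margin=m)
        val = structured_triplet_loss(Ef, Em, ps).item()
        assert val == pytest.approx(math.log(2) / 2, abs=1e-6)

    def test_structured_separated_limit_is_zero(self):
        Ef = Tensor(np.array([[0.0, 0.0], [100.0, 0.0]]))
        Em = Tensor(np.array([[0.0, 0.0], [0.0, 100.0]]))
        ps = PairSets(positives=[(0, 0)], negatives_fixed=[(0, 1)],
                      negatives_moving=[(0, 1)], margin=1.0)
        assert structured_triplet_loss(Ef, Em, ps).item() == 0.0

    def test_structured_empty_positives_warns_and_is_zero(self):
        with pytest.warns(UserWarning):
            val = structured_triplet_loss(Tensor(np.zeros((1, 2))),
                                          Tensor(np.zeros((1, 2))),
                                          PairSets()).item()
        assert val == 0.0

    def test_structured_vectorised_equals_double_loop(self, rng):
        n, D = 10, 6
        Ef = rng.normal(size=(n, D))
        Em = rng.normal(size=(n, D))
        matches = [(i, i) for i in range(n)]
        ps = build_pair_sets(matches, rng.uniform(0, 30, (n, 2)),
                             rng.uniform(0, 30, (n, 2)), margin=0.8)
        got = structured_triplet_loss(Tensor(Ef), Tensor(Em), ps).item()
        want = structured_loss_by_double_loop(Ef, Em, ps)
        assert got == pytest.approx(want, abs=1e-5)

    def test_structured_permutation_invariant(self, rng):
        n = 6
        Ef, Em = rng.normal(size=(n, 4)), rng.normal(size=(n, 4))
        ps = build_pair_sets([(i, i) for i in range(n)],
                             rng.uniform(0, 30, (n, 2)),
                             rng.uniform(0, 30, (n, 2)))
        base = structured_triplet_loss(Tensor(Ef), Tensor(Em), ps).item()
        perm = PairSets(positives=ps.positives[::-1],
                        negatives_fixed=ps.negatives_fixed[::-1],
                        negatives_moving=ps.negatives_moving[::-1],
                        margin=ps.margin)
        assert structured_triplet_loss(Tensor(Ef), Tensor(Em), perm).item() == \
            pytest.approx(base, rel=1e-12)

    def test_monotonicity_in_negative_distance(self, rng):
        """Pushing every negative further away never increases any loss."""
        n = 5
        Ef = rng.normal(size=(n, 3))
        Em = Ef + rng.normal(scale=0.1, size=(n, 3))
        ps = build_pair_sets([(i, i) for i in range(n)],
                             rng.uniform(0, 30, (n, 2)),
                             rng.uniform(0, 30, (n, 2)))
        for kind in ("pairwise", "triplet", "structured"):
            base = matching_loss(Tensor(Ef), Tensor(Em), ps, kind).item()
            spread = matching_loss(Tensor(Ef * 4), Tensor(Em * 4 + 10), ps,
                                   kind).item()
            # scaling apart moves negatives away but also positives; instead
            # move only the non-matching moving rows away from everything
            Em2 = Em.copy()
            for (i, k) in ps.negatives_fixed:
                Em2[k] = Em[k] + 50.0
            # positives whose own row moved are excluded from the claim
            moved = {k for _, k in ps.negatives_fixed}
            if any(j in moved for _, j in ps.positives):
                continue
            far = matching_loss(Tensor(Ef), Tensor(Em2), ps, kind).item()
            assert far <= base + 1e-9


class TestPairSets:
    def test_three_matched_keypoints_enumeration(self, rng):
        pts_f = rng.uniform(0, 30, (3, 2))
        pts_m = rng.uniform(0, 30, (3, 2))
        ps = build_pair_sets([(0, 0), (1, 1), (2, 2)], pts_f, pts_m,
                             exclusion_radius=0)
        assert len(ps.positives) == 3
        assert ps.num_negatives == 12  # 3 anchors x 2 per side
        assert set(ps.positives) & set(ps.negatives_fixed) == set()

    def test_no_matches_empty_positives(self):
        ps = build_pair_sets([], np.zeros((2, 2)), np.zeros((2, 2)))
        assert ps.positives == []

    def test_single_pair_no_negatives(self):
        ps = build_pair_sets([(0, 0)], np.zeros((1, 2)), np.zeros((1, 2)))
        assert len(ps.positives) == 1
        assert ps.num_negatives == 0

    def test_exclusion_radius_drops_ambiguous_negatives(self):
        pts_m = np.array([[0.0, 0.0], [1.0, 0.0], [20.0, 0.0]])
        pts_f = np.array([[0.0, 0.0], [1.0, 0.0], [20.0, 0.0]])
        ps = build_pair_sets([(0, 0)], pts_f, pts_m, exclusion_radius=3.0)
        # moving keypoint 1 is within 3 px of the true match -> excluded
        assert ps.negatives_fixed == [(0, 2)]


class TestTotalLoss:
    def _toy(self, rng):
        P = [Tensor(rng.uniform(0.1, 0.9, (6, 6))) for _ in range(2)]
        Y = [np.round(rng.uniform(0, 1, (6, 6))) for _ in range(2)]
        Ef, Em = Tensor(rng.normal(size=(3, 4))), Tensor(rng.normal(size=(3, 4)))
        ps = build_pair_sets([(i, i) for i in range(3)],
                             rng.uniform(0, 5, (3, 2)), rng.uniform(0, 5, (3, 2)))
        return P, Y, Ef, Em, ps

    def test_zero_weights_zero_loss(self, rng):
        P, Y, Ef, Em, ps = self._toy(rng)
        loss, bd = total_loss(P, Y, Ef, Em, ps, weights=(0, 0, 0))
        assert loss.item() == 0.0

    def test_ce_only_weighting(self, rng):
        P, Y, Ef, Em, ps = self._toy(rng)
        loss, bd = total_loss(P, Y, Ef, Em, ps, weights=(1, 0, 0))
        ce = sum(cross_entropy_loss(p, y).item() for p, y in zip(P, Y)) / 2
        assert loss.item() == pytest.approx(ce, rel=1e-12)

    def test_unit_weights_equal_term_sum(self, rng):
        P, Y, Ef, Em, ps = self._toy(rng)
        loss, bd = total_loss(P, Y, Ef, Em, ps, weights=(1, 1, 1))
        ce = sum(cross_entropy_loss(p, y).item() for p, y in zip(P, Y)) / 2
        dc = sum(dice_loss(p, y).item() for p, y in zip(P, Y)) / 2
        mt = matching_loss(Ef, Em, ps, "structured").item()
        assert loss.item() == pytest.approx(ce + dc + mt, rel=1e-9)
        assert bd["total"] == pytest.approx(loss.item())


class TestMatchingLossGradients:
    @pytest.mark.parametrize("kind", ["pairwise", "triplet", "structured"])
    def test_finite_difference_on_toy_embeddings(self, rng, kind):
        n, D = 5, 3
        Ef = Tensor(rng.normal(size=(n, D)), requires_grad=True)
        Em = Tensor(rng.normal(size=(n, D)), requires_grad=True)
        ps = build_pair_sets([(i, i) for i in range(n)],
                             rng.uniform(0, 30, (n, 2)),
                             rng.uniform(0, 30, (n, 2)))
        loss = matching_loss(Ef, Em, ps, kind)
        loss.backward()
        for t in (Ef, Em):
            fd = finite_difference_grad(
                lambda: float(matching_loss(Ef, Em, ps, kind).data), t.data)
            np.testing.assert_allclose(t.grad, fd, rtol=1e-4, atol=1e-6)


class TestSampleEmbeddingsAt:
    def test_integer_location_returns_pixel_vector(self, rng):
        emb = rng.normal(size=(4, 6, 6))
        out = sample_embeddings_at(Tensor(emb), [[2.0, 3.0]])
        np.testing.assert_allclose(out.data[0], emb[:, 3, 2], atol=1e-12)

    def test_midpoint_is_mean_of_neighbours(self, rng):
        emb = rng.normal(size=(2, 4, 4))
        out = sample_embeddings_at(Tensor(emb), [[1.5, 2.0]])
        np.testing.assert_allclose(out.data[0],
                                   0.5 * (emb[:, 2, 1] + emb[:, 2, 2]), atol=1e-12)
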