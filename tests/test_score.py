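import numpy as np
import pytest

from conftest import make_network
from playnet.network import normalise_with_baseline
from playnet.score import (
    compute_sharing_score,
    grid_scan_score,
    leading_left_eigenvector,
    plates_dominant,
    sharing_score_difference,
)


def power_iteration_left(M, iters=20000, tol=1e-14):
    """Independent oracle: power iteration on the shifted transpose."""
    M = np.asarray(M, dtype=float)
    shift = max(0.0, -np.min(np.diag(M)))
    B = (M + shift * np.eye(len(M))).T
    v = np.ones(len(M)) / np.sqrt(len(M))
    for _ in range(iters):
        nv = B @ v
        nv /= np.linalg.norm(nv)
        if np.linalg.norm(nv - v) < tol:
            v = nv
            break
        v = nv
    return v * np.sign(v[np.argmax(np.abs(v))])


def delivery_network(zm, per_plate=1, extra=()):
    f = zm.food_vertex
    trans = [(f, p) for p in sorted(zm.plate_vertices)] * per_plate + list(extra)
    return normalise_with_baseline(make_network(trans, zm))


class TestLeadingLeftEigenvector:
    def test_uniform_baseline_gives_uniform_vector(self):
        C = np.full((16, 16), 0.01)
        res = leading_left_eigenvector(C)
        assert np.allclose(res.vector, 0.25)
        assert res.value == pytest.approx(0.16)

    def test_raised_diagonal_dominates(self):
        C = np.full((16, 16), 0.01)
        C[3, 3] += 1.0
        res = leading_left_eigenvector(C)
        assert np.argmax(res.vector) == 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_power_iteration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.uniform(0.01, 1.0, size=(16, 16))
        res = leading_left_eigenvector(M)
        oracle = power_iteration_left(M)
        assert np.allclose(res.vector, oracle, atol=1e-10)
        # eigenvector property: v M = lambda v
        assert np.allclose(res.vector @ M, res.value * res.vector, atol=1e-10)

    def test_shift_invariance_for_negative_diagonal(self):
        rng = np.random.default_rng(7)
        M = rng.uniform(0.01, 1.0, size=(16, 16))
        P = M - 0.5 * np.eye(16)
        res_m = leading_left_eigenvector(M)
        res_p = leading_left_eigenvector(P)
        assert np.allclose(res_p.vector, res_m.vector, atol=1e-10)
        assert res_p.value == pytest.approx(res_m.value - 0.5)

    def test_non_finite_rejected(self):
        M = np.full((16, 16), 0.01)
        M[0, 0] = np.nan
        with pytest.raises(ValueError):
            leading_left_eigenvector(M)


class TestPlatesDominant:
    def test_uniform_vector_is_not_dominant(self, zm):
        assert not plates_dominant(np.full(16, 0.25), zm)

    def test_clear_dominance(self, zm):
        v = np.full(16, 0.1)
        v[[4, 5, 6, 7]] = [0.5, 0.4, 0.4, 0.3]
        assert plates_dominant(v, zm)

    def test_tie_with_snap_entry_fails(self, zm):
        v = np.full(16, 0.1)
        v[[4, 5, 6, 7]] = [0.5, 0.4, 0.4, 0.3]
        v[8] = 0.3  # ties the smallest plate entry
        assert not plates_dominant(v, zm)


class TestComputeSharingScore:
    def test_degenerate_baseline_scores_zero(self, zm):
        adj = normalise_with_baseline(make_network([], zm))
        res = compute_sharing_score(adj, zm)
        assert res.degenerate
        assert res.score == 0.0

    def test_even_deliveries_match_grid_oracle(self, zm):
        adj = delivery_network(zm)
        res = compute_sharing_score(adj, zm)
        oracle = grid_scan_score(adj, zm, step=1e-5)
        assert res.score > 0
        assert abs(res.score - oracle) <= 2e-4

    def test_offtask_noise_lowers_score(self, zm):
        clean = compute_sharing_score(delivery_network(zm, per_plate=3), zm)
        offtask = [(1, 2), (2, 3), (3, 1), (12, 13)] * 25
        noisy = compute_sharing_score(
            delivery_network(zm, per_plate=3, extra=offtask), zm
        )
        assert noisy.score < clean.score

    def test_uneven_deliveries_score_lower_than_even(self, zm):
        f = zm.food_vertex
        even = delivery_network(zm, per_plate=2)
        uneven = normalise_with_baseline(
            make_network([(f, 4)] * 5 + [(f, 5), (f, 6), (f, 7)], zm)
        )
        assert (
            compute_sharing_score(uneven, zm).score
            < compute_sharing_score(even, zm).score
        )

    def test_bracket_contains_score_with_flip(self, zm):
        res = compute_sharing_score(delivery_network(zm, per_plate=2), zm)
        lo, hi = res.bracket
        assert hi - lo <= 1e-4
        assert lo <= res.score <= hi

    def test_monotone_response_to_added_deliveries(self, zm):
        # adding evenly distributed deliveries never decreases the score
        f = zm.food_vertex
        psi = sorted(zm.plate_vertices)
        base = [(f, p) for p in psi] * 2 + [(1, 2), (2, 3), (12, 14)] * 4
        prev = compute_sharing_score(
            normalise_with_baseline(make_network(base, zm)), zm
        ).score
        for k in range(1, 21):
            trans = base + [(f, psi[j % 4]) for j in range(k)]
            score = compute_sharing_score(
                normalise_with_baseline(make_network(trans, zm)), zm
            ).score
            assert score >= prev - 2e-4

    def test_step_structure_of_dominance(self, zm):
        from playnet.score import _dominance_on_grid

        adj = delivery_network(zm, per_plate=2, extra=[(1, 2), (3, 1)])
        qs = np.linspace(-1, 1, 101)
        flags = _dominance_on_grid(np.asarray(adj.A), qs, zm)
        assert flags[0] and not flags[-1]
        switch = np.nonzero(~flags)[0][0]
        assert flags[:switch].all() and not flags[switch:].any()

    def test_figure_style_bracketing_on_plate_focused_fixture(self, zm):
        from playnet.score import _dominant_at

        adj = delivery_network(zm, per_plate=3, extra=[(1, 2), (2, 3), (12, 14)])
        A = np.asarray(adj.A)
        assert _dominant_at(A, -0.1, zm)
        assert not _dominant_at(A, 0.1, zm)
        score = compute_sharing_score(adj, zm).score
        assert -0.1 < score < 0.1


class TestSharingScoreDifference:
    def test_no_plate_origin_swipes_gives_zero_difference(self, zm):
        from playnet.network import apply_direct_rules, apply_indirect_rules

        f = zm.food_vertex
        raw = make_network([(f, 4), (f, 5), (f, 6), (f, 7), (1, 2)], zm, variant="raw")
        d = compute_sharing_score(normalise_with_baseline(apply_direct_rules(raw)), zm)
        i = compute_sharing_score(
            normalise_with_baseline(apply_indirect_rules(raw)), zm
        )
        assert sharing_score_difference(i, d) == 0.0

    def test_stacker_session_positive_difference(self, zm):
        from playnet.network import (
            apply_direct_rules,
            apply_indirect_rules,
            build_raw_network,
        )
        from playnet.simulate import simulate_session, stacker_profile
        from playnet.swipes import assemble_swipes

        ev, _ = simulate_session(stacker_profile(seed=5), zm)
        raw = build_raw_network(assemble_swipes(ev), zm)
        d = compute_sharing_score(normalise_with_baseline(apply_direct_rules(raw)), zm)
        i = compute_sharing_score(
            normalise_with_baseline(apply_indirect_rules(raw)), zm
        )
        assert sharing_score_difference(i, d) > 0

    def test_variant_mismatch_rejected(self, zm):
        adj = delivery_network(zm)
        res = compute_sharing_score(adj, zm)
        with pytest.raises(ValueError, match="variant"):
            sharing_score_difference(res, res)
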