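import numpy as np
import pytest

from fcseg.fuzzyconn import (
    AffinityField,
    AffinityParams,
    afc_connectivity,
    affinity,
    fit_object_stats,
    intensity_affinity,
    pair_edge,
    threshold_segmentation,
)


def random_field(rng, rows, cols):
    return AffinityField(
        horizontal=rng.random((rows, cols - 1)),
        vertical=rng.random((rows - 1, cols)),
        shape=(rows, cols),
    )


def brute_force_connectivity(field: AffinityField, seeds, target):
    """Independent oracle: enumerate every simple path from any seed to the
    target and take the max over paths of the min edge affinity."""
    rows, cols = field.shape

    def edge(a, b):
        (r1, c1), (r2, c2) = sorted([a, b])
        if r1 == r2:
            return field.horizontal[r1, c1]
        return field.vertical[r1, c1]

    best = 0.0
    if target in seeds:
        return 1.0

    def dfs(node, strength, visited):
        nonlocal best
        if node == target:
            best = max(best, strength)
            return
        r, c = node
        for nxt in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if 0 <= nxt[0] < rows and 0 <= nxt[1] < cols and nxt not in visited:
                dfs(nxt, min(strength, edge(node, nxt)), visited | {nxt})

    for seed in seeds:
        dfs(seed, 1.0, {seed})
    return best


class TestPairEdge:
    def test_values_and_symmetry(self):
        edge = np.array([[0.2, 0.9], [0.0, 0.0]])
        assert pair_edge(edge, (0, 0), (0, 1)) == 0.9
        assert pair_edge(edge, (0, 1), (0, 0)) == 0.9
        assert pair_edge(edge, (1, 0), (1, 1)) == 0.0
        assert pair_edge(edge, (0, 0), (0, 1), mode="mean") == pytest.approx(0.55)

    def test_rejects_non_adjacent(self):
        edge = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pair_edge(edge, (0, 0), (2, 2))


class TestAffinity:
    def test_maximal_iff_no_edge_and_phase_at_mean(self):
        params = AffinityParams(m_o=2.0, sigma_o=0.3)
        phase = np.full((2, 2), 2.0)
        edge = np.zeros((2, 2))
        field = affinity(phase, edge, params)
        assert np.allclose(field.horizontal, 1.0)
        assert np.allclose(field.vertical, 1.0)
        # perturbing either component strictly lowers the affinity
        phase[0, 1] = 2.2
        field = affinity(phase, edge, params)
        assert field.horizontal[0, 0] < 1.0
        edge2 = np.zeros((2, 2))
        edge2[0, 1] = 0.1
        field = affinity(np.full((2, 2), 2.0), edge2, params)
        assert field.horizontal[0, 0] < 1.0

    def test_hand_calculation(self):
        # omega = 0.5/0.5, E(c,d) = 0.5, |phi - m_o| = 0 and sigma_o:
        # 0.5*0.5 + 0.5*exp(-1/2)
        params = AffinityParams(omega1=0.5, omega2=0.5, m_o=1.0, sigma_o=0.2)
        phase = np.array([[1.0, 1.2]])
        edge = np.array([[0.5, 0.5]])
        field = affinity(phase, edge, params)
        expected = 0.5 * 0.5 + 0.5 * np.exp(-0.5)
        assert field.horizontal[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5533, abs=5e-5)

    def test_full_edge_leaves_only_object_term(self):
        params = AffinityParams(m_o=0.5, sigma_o=0.3)
        phase = np.array([[0.5, 0.9]])
        edge = np.ones((1, 2))
        field = affinity(phase, edge, params)
        g4 = np.exp(-((0.9 - 0.5) ** 2) / (2 * 0.3**2))
        assert field.horizontal[0, 0] == pytest.approx(params.omega2 * g4)
        assert field.horizontal[0, 0] <= params.omega2

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AffinityParams(omega1=0.7, omega2=0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            affinity(np.zeros((3, 3)), np.zeros((3, 4)))


class TestIntensityAffinity:
    def test_constant_image_at_object_mean_is_all_one(self):
        params = AffinityParams(m_o=0.4, sigma_o=0.1)
        field = intensity_affinity(np.full((4, 4), 0.4), params)
        assert np.allclose(field.horizontal, 1.0)
        assert np.allclose(field.vertical, 1.0)

    def test_checkerboard_depresses_affinities(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 * 1.0
        params = AffinityParams(m_o=0.5, sigma_o=10.0)
        field = intensity_affinity(board, params)
        # unit intensity steps kill the whole gradient term; the wide object
        # term contributes omega2 * exp(-0.25/(2*100)) at every pair
        expected = params.omega2 * np.exp(-0.25 / (2 * params.sigma_o**2))
        assert np.allclose(field.horizontal, expected)
        assert np.allclose(field.vertical, expected)
        flat = intensity_affinity(np.full((6, 6), 0.5), params)
        assert (field.horizontal < flat.horizontal).all()


class TestConnectivity:
    def test_seeds_have_unit_connectivity(self):
        rng = np.random.default_rng(0)
        field = random_field(rng, 5, 5)
        conn = afc_connectivity(field, [(0, 0), (4, 4)])
        assert conn.values[0, 0] == 1.0
        assert conn.values[4, 4] == 1.0

    def test_weakest_link_on_a_line(self):
        field = AffinityField(
            horizontal=np.array([[0.9, 0.4]]),
            vertical=np.zeros((0, 3)),
            shape=(1, 3),
        )
        conn = afc_connectivity(field, [(0, 0)])
        assert np.allclose(conn.values, [[1.0, 0.9, 0.4]])

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            field = random_field(rng, 4, 4)
            seed = (int(rng.integers(4)), int(rng.integers(4)))
            conn = afc_connectivity(field, [seed])
            for r in range(4):
                for c in range(4):
                    expected = brute_force_connectivity(field, [seed], (r, c))
                    assert conn.values[r, c] == pytest.approx(expected, abs=1e-15)

    def test_seed_order_and_multi_seed_decomposition(self):
        rng = np.random.default_rng(7)
        field = random_field(rng, 6, 6)
        seeds = [(0, 0), (5, 5), (2, 3)]
        forward = afc_connectivity(field, seeds)
        backward = afc_connectivity(field, seeds[::-1])
        assert np.array_equal(forward.values, backward.values)
        singles = [afc_connectivity(field, [s]).values for s in seeds]
        assert np.allclose(forward.values, np.maximum.reduce(singles))

    def test_monotone_in_affinity(self):
        rng = np.random.default_rng(13)
        field = random_field(rng, 5, 5)
        before = afc_connectivity(field, [(2, 2)]).values
        field.horizontal[1, 2] = min(1.0, field.horizontal[1, 2] + 0.3)
        after = afc_connectivity(field, [(2, 2)]).values
        assert (after >= before - 1e-15).all()

    def test_max_min_local_consistency(self):
        rng = np.random.default_rng(99)
        field = random_field(rng, 6, 6)
        conn = afc_connectivity(field, [(0, 0)]).values
        # every non-seed pixel's value is capped by its best incident link
        for r in range(6):
            for c in range(6):
                if (r, c) == (0, 0):
                    continue
                incident = []
                if c > 0:
                    incident.append(min(conn[r, c - 1], field.horizontal[r, c - 1]))
                if c < 5:
                    incident.append(min(conn[r, c + 1], field.horizontal[r, c]))
                if r > 0:
                    incident.append(min(conn[r - 1, c], field.vertical[r - 1, c]))
                if r < 5:
                    incident.append(min(conn[r + 1, c], field.vertical[r, c]))
                assert conn[r, c] == pytest.approx(max(incident), abs=1e-15)

    def test_input_validation(self):
        rng = np.random.default_rng(1)
        field = random_field(rng, 4, 4)
        with pytest.raises(ValueError):
            afc_connectivity(field, [])
        with pytest.raises(ValueError):
            afc_connectivity(field, [(9, 0)])


class TestThreshold:
    def test_zero_threshold_keeps_everything(self):
        rng = np.random.default_rng(5)
        field = random_field(rng, 5, 5)
        conn = afc_connectivity(field, [(0, 0)])
        assert threshold_segmentation(conn, 0.0).all()

    def test_nested_masks(self):
        rng = np.random.default_rng(6)
        field = random_field(rng, 6, 6)
        conn = afc_connectivity(field, [(3, 3)])
        low = threshold_segmentation(conn, 0.3)
        high = threshold_segmentation(conn, 0.8)
        assert (low | high == low).all()  # high subset of low

    def test_mask_components_contain_seeds(self):
        from scipy import ndimage

        rng = np.random.default_rng(8)
        field = random_field(rng, 8, 8)
        seeds = [(1, 1), (6, 6)]
        conn = afc_connectivity(field, seeds)
        mask = threshold_segmentation(conn, 0.7)
        labelled, n = ndimage.label(mask)
        seed_labels = {labelled[s] for s in seeds}
        assert set(range(1, n + 1)) <= seed_labels


class TestFitObjectStats:
    def test_mean_and_inflated_spread(self):
        rng = np.random.default_rng(2)
        phase = rng.normal(2.4, 0.1, (50, 50))
        roi = np.zeros((50, 50), dtype=bool)
        roi[10:40, 10:40] = True
        m_o, sigma_o = fit_object_stats(phase, roi)
        assert m_o == pytest.approx(phase[roi].mean())
        assert sigma_o == pytest.approx(3 * phase[roi].std())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            fit_object_stats(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))
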