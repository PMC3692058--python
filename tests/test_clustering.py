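import numpy as np
import pytest

from ribotherm import DbscanParams, cluster_summary, dbscan_1d, density_profile
from ribotherm.clustering import Cluster


def brute_force_dbscan(positions, eps, min_pts):
    """Textbook DBSCAN with explicit neighbourhoods, ascending seed order.

    Returns (list of member tuples sorted by start, noise set).
    """
    pts = sorted(set(positions))
    neighbors = {
        p: [q for q in pts if abs(q - p) <= eps] for p in pts
    }
    core = {p for p in pts if len(neighbors[p]) >= min_pts}
    label = {}
    cluster_id = 0
    for p in pts:
        if p in label or p not in core:
            continue
        cluster_id += 1
        queue = [p]
        label[p] = cluster_id
        while queue:
            q = queue.pop(0)
            if q not in core:
                continue
            for r in neighbors[q]:
                if r not in label:
                    label[r] = cluster_id
                    queue.append(r)
    clusters = []
    for cid in range(1, cluster_id + 1):
        members = tuple(sorted(p for p, l in label.items() if l == cid))
        clusters.append(members)
    noise = {p for p in pts if p not in label}
    return sorted(clusters), noise


class TestDbscan1d:
    def test_sparse_points_are_noise(self):
        assert dbscan_1d({10, 500}) == []

    def test_five_adjacent_positions_form_one_cluster(self):
        clusters = dbscan_1d({100, 101, 102, 103, 104})
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.density, c.length) == (100, 104, 1.0, 5)

    def test_two_separated_groups(self):
        clusters = dbscan_1d({1, 3, 5, 7, 9, 200, 203, 206, 209, 212})
        assert [(c.start, c.end) for c in clusters] == [(1, 9), (200, 212)]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_pts = rng.integers(0, 41)
            line = rng.integers(20, 301)
            positions = set(rng.integers(1, line + 1, size=n_pts).tolist())
            eps = int(rng.integers(1, 16))
            min_pts = int(rng.integers(1, 8))
            ours = dbscan_1d(positions, DbscanParams(eps, min_pts))
            expected, noise = brute_force_dbscan(positions, eps, min_pts)
            assert [c.members for c in ours] == expected
            clustered = {p for c in ours for p in c.members}
            assert clustered == set(positions) - noise

    def test_permutation_invariance(self):
        positions = [13, 2, 7, 5, 3, 11, 90, 91, 92, 93, 94]
        a = dbscan_1d(positions)
        b = dbscan_1d(list(reversed(positions)))
        assert [c.members for c in a] == [c.members for c in b]

    def test_members_disjoint_and_spans_ordered(self):
        clusters = dbscan_1d(set(range(1, 30)) | set(range(100, 130)))
        seen = set()
        for c in clusters:
            assert not (seen & set(c.members))
            seen |= set(c.members)
        starts = [c.start for c in clusters]
        assert starts == sorted(starts)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DbscanParams(eps=0)
        with pytest.raises(ValueError):
            DbscanParams(min_pts=0)


class TestClusterSummary:
    def test_empty(self):
        s = cluster_summary([])
        assert s.n_clusters == 0 and s.avg_density is None and s.avg_length is None

    def test_single_dense_cluster(self):
        c = Cluster(start=100, end=104, members=(100, 101, 102, 103, 104))
        s = cluster_summary([c])
        assert (s.n_clusters, s.avg_density, s.avg_length) == (1, 1.0, 5.0)

    def test_unweighted_averages(self):
        c1 = Cluster(start=1, end=10, members=tuple(range(1, 10, 2)))  # 5/10
        c2 = Cluster(start=50, end=54, members=(50, 51, 52, 53, 54))  # 5/5
        s = cluster_summary([c1, c2])
        assert s.avg_density == pytest.approx(0.75)
        assert s.avg_length == pytest.approx(7.5)


class TestDensityProfile:
    def test_no_positions_gives_zero_profile(self):
        prof = density_profile(set(), 100, eps=11)
        assert prof.shape == (78,) and np.all(prof == 0.0)

    def test_all_positions_give_hundred(self):
        prof = density_profile(set(range(1, 101)), 100, eps=11)
        assert np.all(prof == 100.0)

    def test_block_of_significant_positions(self):
        prof = density_profile(set(range(1, 24)), 100, eps=11)
        assert prof[0] == pytest.approx(100.0)
        assert prof[23] == pytest.approx(0.0)  # window 24..46 holds none
        # window 2..24 holds positions 2..23 -> 22 of 23
        assert prof[1] == pytest.approx(100.0 * 22 / 23)

    def test_short_sequence_falls_back_to_single_window(self):
        prof = density_profile({1, 2}, 10, eps=11)
        assert prof.shape == (1,)
        assert prof[0] == pytest.approx(20.0)
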