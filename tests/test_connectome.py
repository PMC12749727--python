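"""Connectome container, I/O, and structural manipulations."""

import numpy as np
import pandas as pd
import pytest

from hiertime import (
    Connectome,
    SyntheticSpec,
    load_connectome,
    remove_feedback,
    shuffle_fln,
    synth_connectome,
    write_connectome,
)
from hiertime.connectome import ConnectomeError


def _write_fixture(tmp_path, conn, **kw):
    return write_connectome(conn, tmp_path, **kw)


@pytest.fixture
def conn3():
    rng = np.random.default_rng(5)
    fln = rng.uniform(0.1, 1.0, (3, 3))
    np.fill_diagonal(fln, 0.0)
    sln = rng.uniform(0, 1, (3, 3))
    pos = rng.uniform(0, 10, (3, 3))
    dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    return Connectome(areas=["V1", "V2", "PG"], fln=fln, sln=sln, dist=dist)


class TestLoad:
    def test_roundtrip_preserves_matrices(self, tmp_path, conn3):
        paths = _write_fixture(tmp_path, conn3)
        loaded = load_connectome(paths["fln"], paths["sln"], paths["dist"])
        np.testing.assert_allclose(loaded.fln, conn3.fln, rtol=1e-11)
        np.testing.assert_allclose(loaded.sln, conn3.sln, rtol=1e-11)
        np.testing.assert_allclose(loaded.dist, conn3.dist, rtol=1e-11)
        assert loaded.areas == conn3.areas
        # second roundtrip is bit-identical at the writer's precision
        paths2 = _write_fixture(tmp_path / "again", loaded)
        assert paths2["fln"].read_text() == paths["fln"].read_text()

    def test_normalization_makes_rows_sum_to_one(self, tmp_path, conn3):
        paths = _write_fixture(tmp_path, conn3)
        loaded = load_connectome(
            paths["fln"], paths["sln"], paths["dist"], normalize_rows=True
        )
        np.testing.assert_allclose(loaded.fln.sum(axis=1), 1.0, atol=1e-9)

    def test_permuted_sln_order_gives_same_connectome(self, tmp_path, conn3):
        paths = _write_fixture(tmp_path, conn3)
        sln = pd.read_csv(paths["sln"], index_col=0)
        perm = ["PG", "V1", "V2"]
        sln.loc[perm, perm].to_csv(tmp_path / "sln_perm.csv")
        a = load_connectome(paths["fln"], paths["sln"], paths["dist"])
        b = load_connectome(paths["fln"], tmp_path / "sln_perm.csv", paths["dist"])
        np.testing.assert_allclose(a.sln, b.sln, rtol=1e-11)
        assert a.areas == b.areas

    def test_missing_area_is_named_in_error(self, tmp_path, conn3):
        paths = _write_fixture(tmp_path, conn3)
        dist = pd.read_csv(paths["dist"], index_col=0)
        dist.drop(index="PG", columns="PG").to_csv(tmp_path / "dist_short.csv")
        with pytest.raises(ConnectomeError, match="PG"):
            load_connectome(paths["fln"], paths["sln"], tmp_path / "dist_short.csv")

    def test_negative_fln_rejected(self, tmp_path, conn3):
        paths = _write_fixture(tmp_path, conn3)
        fln = pd.read_csv(paths["fln"], index_col=0)
        fln.iloc[0, 1] = -0.5
        fln.to_csv(tmp_path / "fln_neg.csv")
        with pytest.raises(ConnectomeError, match="negative"):
            load_connectome(tmp_path / "fln_neg.csv", paths["sln"], paths["dist"])

    def test_nonzero_diagonal_needs_repair_flag(self, tmp_path, conn3):
        paths = _write_fixture(tmp_path, conn3)
        fln = pd.read_csv(paths["fln"], index_col=0)
        fln.iloc[1, 1] = 0.3
        fln.to_csv(tmp_path / "fln_diag.csv")
        with pytest.raises(ConnectomeError, match="diagonal"):
            load_connectome(tmp_path / "fln_diag.csv", paths["sln"], paths["dist"])
        fixed = load_connectome(
            tmp_path / "fln_diag.csv", paths["sln"], paths["dist"],
            repair_diagonal=True,
        )
        assert fixed.fln[1, 1] == 0.0

    def test_annotations_are_attached(self, tmp_path):
        conn = synth_connectome(SyntheticSpec(n_areas=5, seed=1))
        paths = write_connectome(conn, tmp_path)
        loaded = load_connectome(
            paths["fln"], paths["sln"], paths["dist"],
            annotations_path=paths["annotations"],
        )
        np.testing.assert_allclose(loaded.hierarchy_exp, conn.hierarchy_exp, rtol=1e-10)
        np.testing.assert_allclose(loaded.positions, conn.positions, rtol=1e-10)


class TestShuffle:
    def test_preserves_offdiagonal_multiset_and_zero_diagonal(self, conn3):
        sh = shuffle_fln(conn3, seed=3)
        off = ~np.eye(3, dtype=bool)
        assert sorted(sh.fln[off]) == pytest.approx(sorted(conn3.fln[off]))
        assert np.all(np.diag(sh.fln) == 0)
        np.testing.assert_array_equal(sh.sln, conn3.sln)
        np.testing.assert_array_equal(sh.dist, conn3.dist)

    def test_same_seed_is_deterministic(self, conn3):
        a = shuffle_fln(conn3, seed=11)
        b = shuffle_fln(conn3, seed=11)
        np.testing.assert_array_equal(a.fln, b.fln)

    def test_two_area_shuffle_has_exactly_two_arrangements(self):
        fln = np.array([[0.0, 0.3], [0.7, 0.0]])
        conn = Connectome(
            areas=["A", "B"], fln=fln, sln=np.full((2, 2), 0.5),
            dist=np.array([[0.0, 1.0], [1.0, 0.0]]),
        )
        # brute-force oracle: the only permutations of two off-diagonal
        # entries are identity and swap
        expected = {(0.3, 0.7), (0.7, 0.3)}
        seen = set()
        for seed in range(20):
            sh = shuffle_fln(conn, seed)
            seen.add((sh.fln[0, 1], sh.fln[1, 0]))
        assert seen <= expected
        assert len(seen) == 2  # both arrangements occur across seeds

    def test_positionwise_mean_converges_to_grand_mean(self, conn3):
        off = ~np.eye(3, dtype=bool)
        vals = conn3.fln[off]
        grand = vals.mean()
        n = 1000
        acc = np.zeros_like(conn3.fln)
        for seed in range(n):
            acc += shuffle_fln(conn3, seed).fln
        pos_means = (acc / n)[off]
        se = vals.std(ddof=1) / np.sqrt(n)  # SE of a position's mean over n shuffles
        assert np.all(np.abs(pos_means - grand) < 3 * se)


class TestRemoveFeedback:
    def test_only_subthreshold_sln_entries_zeroed(self):
        fln = np.array([[0.0, 0.2], [0.5, 0.0]])
        sln = np.array([[0.5, 0.4], [0.6, 0.5]])
        conn = Connectome(areas=["A", "B"], fln=fln, sln=sln,
                          dist=np.array([[0.0, 1.0], [1.0, 0.0]]))
        out = remove_feedback(conn)
        assert out.fln[0, 1] == 0.0  # sln 0.4 < 0.5: feedback, deleted
        assert out.fln[1, 0] == 0.5  # sln 0.6: feedforward, kept

    def test_no_deletion_when_all_feedforward(self, conn3):
        conn3.sln[:] = 0.9
        out = remove_feedback(conn3)
        np.testing.assert_array_equal(out.fln, conn3.fln)

    def test_full_deletion_when_all_feedback(self, conn3):
        conn3.sln[:] = 0.1
        out = remove_feedback(conn3)
        assert np.all(out.fln == 0)
        assert sorted(out.zero_rows) == [0, 1, 2]  # flagged, not an error

    def test_idempotent(self, conn3):
        once = remove_feedback(conn3)
        twice = remove_feedback(once)
        np.testing.assert_array_equal(once.fln, twice.fln)

    def test_rows_are_not_renormalized(self, conn3):
        out = remove_feedback(conn3)
        kept = out.fln > 0
        np.testing.assert_array_equal(out.fln[kept], conn3.fln[kept])


class TestValidation:
    def test_asymmetric_distance_rejected(self, conn3):
        dist = conn3.dist.copy()
        dist[0, 1] += 1.0
        with pytest.raises(ConnectomeError, match="symmetric"):
            Connectome(areas=conn3.areas, fln=conn3.fln, sln=conn3.sln, dist=dist)

    def test_sln_out_of_range_rejected(self, conn3):
        sln = conn3.sln.copy()
        sln[0, 1] = 1.5
        with pytest.raises(ConnectomeError, match="SLN"):
            Connectome(areas=conn3.areas, fln=conn3.fln, sln=sln, dist=conn3.dist)
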