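import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import decograd as dg
from decograd.meta_maps import MetaAnalyticMap
from decograd.pseudo_maps import PeakPoint, PseudoActivationMap

from conftest import smooth_sphere_map


def _map(label, values):
    return MetaAnalyticMap(labels=[label], values=values)


class TestCorrelate:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(0)
        target = rng.normal(size=50)
        maps = [_map("same", target.copy()), _map("anti", -target), _map("noise", rng.normal(size=50))]
        ranked = dg.correlate(target, maps)
        assert ranked[0] == ("same", pytest.approx(1.0))
        assert ranked[-1] == ("anti", pytest.approx(-1.0))

    def test_three_vertex_hand_pearson(self):
        ranked = dg.correlate(np.array([1.0, 2.0, 3.0]), [_map("m", np.array([1.0, 2.0, 2.0]))])
        assert ranked[0][1] == pytest.approx(np.sqrt(3) / 2, abs=1e-9)
        assert ranked[0][1] == pytest.approx(0.866, abs=1e-3)

    def test_zero_variance_map_excluded(self):
        target = np.array([1.0, 2.0, 3.0])
        ranked = dg.correlate(target, [_map("flat", np.ones(3)), _map("ok", target)])
        assert [label for label, _ in ranked] == ["ok"]

    def test_tie_order_by_label(self):
        target = np.array([1.0, 2.0, 3.0])
        ranked = dg.correlate(target, [_map("b", target * 2), _map("a", target + 5)])
        assert [label for label, _ in ranked] == ["a", "b"]


class TestSpinNulls:
    def test_rows_are_bijections(self):
        mesh = dg.synth_sphere(300, medial_fraction=0.1, seed=0)
        nulls = dg.spin_nulls(mesh, n_perm=20, seed=1)
        n_cx = mesh.n_cortex
        for row in nulls.indices:
            assert np.array_equal(np.sort(row), np.arange(n_cx))

    def test_seed_reproducibility(self):
        mesh = dg.synth_sphere(200, medial_fraction=0.0, seed=0)
        a = dg.spin_nulls(mesh, n_perm=5, seed=7)
        b = dg.spin_nulls(mesh, n_perm=5, seed=7)
        np.testing.assert_array_equal(a.indices, b.indices)
        c = dg.spin_nulls(mesh, n_perm=5, seed=8)
        assert not np.array_equal(a.indices, c.indices)

    def test_value_multiset_preserved(self):
        mesh = dg.synth_sphere(250, medial_fraction=0.1, seed=0)
        values = smooth_sphere_map(mesh, seed=3)[mesh.cortex_mask]
        nulls = dg.spin_nulls(mesh, n_perm=10, seed=2)
        for row in nulls.indices:
            np.testing.assert_array_equal(np.sort(values[row]), np.sort(values))

    def test_autocorrelation_preserved(self):
        """Moran-type statistic of spun maps stays within 20% of the original.

        Run without a medial wall so the spin is a pure rotation; the
        fixed-wall boundary necessarily scrambles a thin rim of vertices.
        """
        mesh = dg.synth_sphere(600, medial_fraction=0.0, seed=0)
        cortex = mesh.cortex_mask
        coords = mesh.coordinates[cortex]
        values = smooth_sphere_map(mesh, seed=4, n_bumps=4, scale=0.9)[cortex]
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        w = (d2 < np.partition(d2, 6, axis=1)[:, [6]]).astype(float)  # ~6-NN graph
        w = (w + w.T) / 2

        def moran(v):
            z = v - v.mean()
            return (coords.shape[0] / w.sum()) * (z @ w @ z) / (z @ z)

        base = moran(values)
        nulls = dg.spin_nulls(mesh, n_perm=10, seed=5)
        spun = np.array([moran(values[row]) for row in nulls.indices])
        assert np.all(np.abs(spun - base) / abs(base) < 0.2)

    def test_too_few_vertices(self):
        mesh = dg.synth_sphere(30, medial_fraction=0.0, seed=0)
        mesh.cortex_mask[:] = False
        mesh.cortex_mask[:2] = True
        with pytest.raises(ValueError):
            dg.spin_nulls(mesh, n_perm=2, seed=0)


class TestPermPvalue:
    def test_literal_fraction(self):
        assert dg.perm_pvalue(0.25, np.array([0.1, 0.2, 0.3, 0.4])) == 0.5
        assert dg.perm_pvalue(0.9, np.array([0.1, 0.2, 0.3, 0.4])) == 0.0
        nulls = np.linspace(-1, 1, 1001)
        assert dg.perm_pvalue(0.0, nulls) == pytest.approx(0.5, abs=0.01)

    def test_plus_one_estimator_never_zero(self):
        assert dg.perm_pvalue(2.0, np.zeros(99), estimator="plus_one") == pytest.approx(0.01)

    def test_empty_nulls(self):
        with pytest.raises(ValueError):
            dg.perm_pvalue(0.1, np.array([]))


def _bh_oracle(p, alpha=0.05):
    """Textbook step-up BH, written independently."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    k = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= alpha * rank / m:
            k = rank
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return q, reject


class TestFDR:
    def test_hand_example(self):
        q, reject = dg.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert reject.all()

    def test_all_ones_none_significant(self):
        _, reject = dg.fdr_bh(np.ones(10))
        assert not reject.any()

    def test_single_p(self):
        _, reject = dg.fdr_bh(np.array([0.04]))
        assert reject[0]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=100))
    def test_matches_stepup_oracle(self, pvals):
        p = np.array(pvals)
        q, reject = dg.fdr_bh(p)
        oq, oreject = _bh_oracle(p)
        np.testing.assert_allclose(q, oq, atol=1e-12)
        np.testing.assert_array_equal(reject, oreject)


def _targets_from(values_list):
    return [
        PseudoActivationMap(
            segment_id=i, values=v, sigma=1.0, peak=PeakPoint(segment_id=i, coordinates=np.zeros(1))
        )
        for i, v in enumerate(values_list)
    ]


class TestDecode:
    def test_table_cardinality_and_columns(self, small_world):
        w = small_world
        targets = _targets_from([smooth_sphere_map(w.mesh, seed=s) for s in (1, 2, 3)])
        maps = [_map(f"m{s}", smooth_sphere_map(w.mesh, seed=10 + s)) for s in range(4)]
        table = dg.decode(targets, maps, w.mesh, n_perm=20, seed=0)
        assert len(table) == 3 * 4
        assert set(table.columns) == {"segment_id", "label", "r", "p", "q", "significant"}
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
        assert (table["significant"] == (table["q"] < 0.05)).all()

    def test_deterministic_given_seed(self, small_world):
        w = small_world
        targets = _targets_from([smooth_sphere_map(w.mesh, seed=1)])
        maps = [_map("m", smooth_sphere_map(w.mesh, seed=2))]
        t1 = dg.decode(targets, maps, w.mesh, n_perm=30, seed=4)
        t2 = dg.decode(targets, maps, w.mesh, n_perm=30, seed=4)
        assert t1.equals(t2)

    def test_null_pvalues_approximately_uniform(self):
        """KS distance of null-target permutation p-values from U(0,1)."""
        mesh = dg.synth_sphere(250, medial_fraction=0.1, seed=0)
        rng = np.random.default_rng(6)
        maps = [_map(f"m{j}", smooth_sphere_map(mesh, seed=100 + j)) for j in range(5)]
        targets = _targets_from(
            [smooth_sphere_map(mesh, seed=200 + s) + 0.1 * rng.normal(size=mesh.n_vertices) for s in range(20)]
        )
        table = dg.decode(targets, maps, mesh, n_perm=100, seed=1)
        p = np.sort(table["p"].to_numpy())
        grid = (np.arange(p.size) + 1) / p.size
        ks = np.max(np.abs(p - grid))
        assert ks < 0.15


class TestCorrelationProfile:
    def test_two_points_and_mean(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "segment_id": [0, 0, 1, 1],
                "label": ["a", "b", "a", "b"],
                "r": [0.9, 0.2, 0.1, 0.6],
                "p": [0.0] * 4,
                "q": [0.0] * 4,
                "significant": [True] * 4,
            }
        )
        profile = dg.correlation_profile(table, peaks={0: -2.0, 1: 2.0})
        assert len(profile) == 2
        assert profile.loc[0, "top_r"] == 0.9 and profile.loc[0, "top_label"] == "a"
        assert profile.loc[1, "top_r"] == 0.6 and profile.loc[1, "x"] == 2.0
        assert profile.attrs["mean"] == pytest.approx(0.75)

    def test_u_shape_on_synthetic_decoding(self, small_world):
        """Terminal segments decode better than interior ones for k >= 5."""
        w = small_world
        g = dg.gradients_from_connectome(w.connectome, seed=5)
        seg = dg.segment_kmeans(g.components[:, 0], 6, seed=0)
        pseudo = dg.build_map_set(seg)
        for pm in pseudo:
            vals = np.zeros(w.mesh.n_vertices)
            vals[w.mesh.cortex_mask] = pm.values
            pm.values = vals
        model = dg.TopicModel(
            word_topic=w.truth.topic_word,
            doc_topic=w.truth.doc_topic,
            vocabulary=w.corpus.vocabulary,
            doc_ids=w.corpus.doc_ids,
        )
        maps, _ = dg.build_topic_maps(model, w.study_maps)
        maps = [m for m in maps if np.std(m.values[w.mesh.cortex_mask]) > 0]
        table = dg.decode(pseudo, maps, w.mesh, n_perm=10, seed=0)
        profile = dg.correlation_profile(table)
        tops = profile["top_r"].to_numpy()
        assert min(tops[0], tops[-1]) > np.median(tops[1:-1])
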