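"""Breadth-of-tuning measures, clustering and ensemble analysis.

Clustering heights are checked against a brute-force O(n^3) agglomeration
and the MDS embedding against a direct eigendecomposition reconstruction.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gustnet.coding import (
    classical_mds,
    cluster_profiles,
    ensemble_mds,
    entropy_h,
    noise_signal_ratio,
    profile_stability,
    tuning_metrics,
)
from gustnet.core import ValidationError

from conftest import make_profile


def brute_average_linkage_heights(D: np.ndarray) -> list[float]:
    """Direct agglomeration: merge closest pair, average over members."""
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (None, None, math.inf)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if d < best[2]:
                    best = (a, b, d)
        a, b, d = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestEntropy:
    def test_uniform_five_vector(self):
        h, p = entropy_h([0.2, 0.2, 0.2, 0.2, 0.2])
        assert h == pytest.approx(1.43 * math.log10(5), abs=1e-12)
        assert h == pytest.approx(0.9995, abs=1e-3)

    def test_single_stimulus_near_zero(self):
        h, _ = entropy_h([1.0, 0.0, 0.0, 0.0, 0.0])
        assert h == pytest.approx(0.0, abs=1e-4)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(1000):
            r = rng.random(5) + 1e-3
            h, p = entropy_h(r)
            direct = -1.43 * sum(pi * math.log10(pi) for pi in r / r.sum())
            assert abs(h - direct) < 1e-10

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8),
        st.floats(0.1, 50.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance_and_bounds(self, resp, scale):
        h1, _ = entropy_h(resp)
        h2, _ = entropy_h([scale * r for r in resp])
        assert h1 == pytest.approx(h2, rel=1e-9)
        assert -1e-12 <= h1 <= 1.43 * math.log10(len(resp)) + 1e-12

    def test_all_nonpositive_is_undefined(self):
        h, _ = entropy_h([0.0, -2.0, 0.0, 0.0, 0.0])
        assert math.isnan(h)


class TestNoiseSignal:
    def test_second_best_over_best(self):
        assert noise_signal_ratio([40.0, 10.0, 2.0, 0.0]) == pytest.approx(0.25)

    def test_negatives_floored_at_zero(self):
        assert noise_signal_ratio([40.0, -5.0, -1.0, 0.0]) == pytest.approx(0.0)

    def test_undefined_when_best_nonpositive(self):
        assert math.isnan(noise_signal_ratio([0.0, -1.0, -2.0]))

    def test_tuning_metrics_excludes_umami(self, panel_a):
        # MSGai is the second-best response but excluded from N:S
        prof = make_profile("u1", panel_a, control=[40.0, 30.0, 10.0, 2.0, 0.0])
        tm = tuning_metrics(prof, "control")
        assert tm.ns_ratio == pytest.approx(10.0 / 40.0)
        assert tm.n_significant == 3


class TestClustering:
    def test_identical_profiles_merge_at_zero(self, panel_a):
        profs = [
            make_profile("a1", panel_a, [10, 0, 0, 0, 0]),
            make_profile("a2", panel_a, [10, 0, 0, 0, 0]),
            make_profile("b1", panel_a, [0, 0, 0, 0, 10]),
        ]
        cl = cluster_profiles(profs)
        assert cl.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_final_merge_matches_pearson_oracle(self, panel_a):
        a, b = [1.0, 0, 0, 0, 0], [0, 0, 0, 0, 1.0]
        profs = [
            make_profile("a1", panel_a, a),
            make_profile("a2", panel_a, a),
            make_profile("b1", panel_a, b),
            make_profile("b2", panel_a, b),
        ]
        cl = cluster_profiles(profs)
        r = np.corrcoef(a, b)[0, 1]
        assert cl.linkage[-1, 2] == pytest.approx(1 - r, abs=1e-12)
        assert cl.scree[:2] == pytest.approx([0.0, 0.0], abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_heights_match_brute_force_agglomeration(self, n, panel_a, rng):
        for rep in range(6):
            X = rng.random((n, 5)) * 20
            profs = [make_profile(f"u{i}", panel_a, row) for i, row in enumerate(X)]
            cl = cluster_profiles(profs)
            D = 1 - np.corrcoef(X)
            expect = brute_average_linkage_heights(D)
            assert np.allclose(np.sort(cl.scree), np.sort(expect), atol=1e-10)

    def test_constant_profile_excluded_with_record(self, panel_a):
        profs = [
            make_profile("flat", panel_a, [5, 5, 5, 5, 5]),
            make_profile("u1", panel_a, [10, 0, 0, 0, 0]),
            make_profile("u2", panel_a, [0, 10, 0, 0, 0]),
            make_profile("u3", panel_a, [0, 0, 10, 0, 0]),
        ]
        cl = cluster_profiles(profs)
        assert cl.excluded_ids == ["flat"]
        assert len(cl.unit_ids) == 3

    def test_scale_invariance_of_heights(self, panel_a, rng):
        X = rng.random((5, 5)) * 10
        p1 = [make_profile(f"u{i}", panel_a, r) for i, r in enumerate(X)]
        p2 = [make_profile(f"u{i}", panel_a, 7.3 * r) for i, r in enumerate(X)]
        assert np.allclose(
            cluster_profiles(p1).scree, cluster_profiles(p2).scree, atol=1e-12
        )

    def test_newick_export_has_all_leaves(self, panel_a, rng):
        X = rng.random((4, 5))
        profs = [make_profile(f"u{i}", panel_a, r) for i, r in enumerate(X)]
        nwk = cluster_profiles(profs).to_newick()
        assert nwk.endswith(";")
        for i in range(4):
            assert f"u{i}" in nwk


class TestStability:
    def test_pure_divisive_gives_unit_correlation(self, panel_a):
        c = [40.0, 20.0, 8.0, 2.0, 0.0]
        prof = make_profile("u1", panel_a, c, light=[0.5 * x for x in c])
        r = profile_stability([prof])["u1"]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_sign_inverted_profile(self, panel_a):
        c = [40.0, 20.0, 8.0, 2.0, 1.0]
        prof = make_profile("u1", panel_a, c, light=[-x for x in c])
        assert profile_stability([prof])["u1"] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_flagged_nan(self, panel_a):
        prof = make_profile("u1", panel_a, [3, 3, 3, 3, 3], light=[1, 2, 3, 4, 5])
        assert math.isnan(profile_stability([prof])["u1"])


class TestMDS:
    def test_two_embeddable_distances_reproduced(self, rng):
        pts = rng.random((6, 2)) * 5
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = classical_mds(D, dims=2)
        D2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        pts = rng.random((5, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        c1, c2 = classical_mds(D), classical_mds(D)
        assert np.array_equal(c1, c2)
        assert (c1[0] >= 0).all()

    def test_perfectly_correlated_stimuli_coincide(self, panel_a):
        # second stimulus response = 2x first across all neurons -> r = 1
        base = np.array([[1, 2, 5, 1, 0.5], [3, 6, 1, 2, 1], [2, 4, 3, 3, 2]], float)
        profs = []
        for i, row in enumerate(base):
            vec = [row[0], 2 * row[0], row[2], row[3], row[4]]
            profs.append(make_profile(f"u{i}", panel_a, vec, light=list(vec)))
        ens = ensemble_mds(profs)
        a = ens.coords_for("SUC", "control")
        b = ens.coords_for("MSGai", "control")
        assert np.allclose(a, b, atol=1e-8)

    def test_pure_divisive_cross_condition_unity(self, panel_a, rng):
        profs = []
        for i in range(5):
            c = rng.random(5) * 30
            profs.append(make_profile(f"u{i}", panel_a, c, light=0.5 * c))
        ens = ensemble_mds(profs)
        for s, r in ens.cross_condition().items():
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_too_few_neurons_rejected(self, panel_a):
        profs = [make_profile("u0", panel_a, [1, 2, 3, 4, 5], light=[1, 2, 3, 4, 5])]
        with pytest.raises(ValidationError):
            ensemble_mds(profs)
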