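import numpy as np
import pandas as pd
import pytest

from vinotyper.calling import (
    CallingParams,
    GenotypeCaller,
    biweight_location_scale,
    call_probe,
    compute_group_stats,
    confidence_scores,
    fit_contrast_mixture,
    friends_of_friends_assign,
    initial_assignment,
    label_components,
    select_component_count,
    silhouette_score,
)
from vinotyper.io import IntensityTable
from vinotyper.sim import SimulationConfig, simulate_dataset

from conftest import noiseless_config


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_silhouette(points, labels):
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    labels = np.asarray(labels)
    scores = []
    for i in range(len(pts)):
        own = [j for j in range(len(pts)) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(pts[i] - pts[j]) for j in range(len(pts)) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))


def brute_force_accretion(points, labels, scales):
    pts = np.asarray(points, dtype=float) / scales
    labels = list(labels)
    while -1 in labels:
        best = None
        for i, li in enumerate(labels):
            if li != -1:
                continue
            for j, lj in enumerate(labels):
                if lj == -1:
                    continue
                d = np.linalg.norm(pts[i] - pts[j])
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        labels[best[1]] = labels[best[2]]
    return np.array(labels)


def brute_force_biweight(values, c=5.0, eps=1e-4):
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    num_w = den_w = 0.0
    sum_sq = 0.0
    den_scale = 0.0
    n_in = 0
    for xi in x:
        u = (xi - med) / (c * mad + eps)
        if abs(u) < 1:
            w = (1 - u * u) ** 2
            num_w += w * xi
            den_w += w
            sum_sq += (xi - med) ** 2 * (1 - u * u) ** 4
            den_scale += (1 - u * u) * (1 - 5 * u * u)
            n_in += 1
    if n_in == 0:
        return med, 0.0
    loc = num_w / den_w
    scale = np.sqrt(len(x) * sum_sq / den_scale**2) if den_scale > 0 else 0.0
    return loc, scale


# ---------------------------------------------------------------------------
# EM mixture


class TestMixture:
    def test_degenerate_all_equal_forces_k1(self):
        with pytest.warns(UserWarning, match="forcing k=1"):
            fit = fit_contrast_mixture(np.full(10, 0.3), 2)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(0.3)
        assert fit.variances[0] == pytest.approx(CallingParams().variance_floor)

    def test_two_point_masses_recovered(self):
        x = np.array([-0.6] * 10 + [0.6] * 10)
        fit = fit_contrast_mixture(x, 2)
        assert sorted(fit.means) == pytest.approx([-0.6, 0.6], abs=1e-6)
        assert set(np.round(fit.posteriors.ravel(), 6)) <= {0.0, 1.0}

    def test_three_component_parameter_recovery(self, rng):
        x = np.concatenate(
            [rng.normal(-0.6, 0.05, 100), rng.normal(0.0, 0.05, 100), rng.normal(0.6, 0.05, 100)]
        )
        fit = fit_contrast_mixture(x, 3)
        assert np.sort(fit.means) == pytest.approx([-0.6, 0.0, 0.6], abs=0.02)

    def test_loglik_monotone_nondecreasing(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 60) + rng.choice([-0.5, 0.5], 60)
            for k in (1, 2, 3):
                fit = fit_contrast_mixture(x, k)
                assert (np.diff(fit.log_likelihoods) >= -1e-8).all()


class TestSilhouetteAndSelection:
    def test_trivial_values(self):
        # two tight, far-apart pairs approach 1
        pts = np.array([0.0, 0.001, 10.0, 10.001])
        assert silhouette_score(pts, [0, 0, 1, 1]) > 0.99
        # all identical points: a == b == 0 -> 0
        assert silhouette_score(np.zeros(6), [0, 0, 0, 1, 1, 1]) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            silhouette_score(np.arange(4.0), [1, 1, 1, 1])

    def test_six_point_worked_example_matches_oracle(self):
        pts = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        labels = [0, 0, 0, 1, 1, 1]
        assert silhouette_score(pts, labels) == pytest.approx(brute_force_silhouette(pts, labels))

    def test_fuzz_matches_brute_force(self, rng):
        for _ in range(120):
            n = int(rng.integers(4, 25))
            pts = rng.normal(0, 1, (n, int(rng.integers(1, 3))))
            labels = rng.integers(0, int(rng.integers(2, 4)), n)
            if len(np.unique(labels)) < 2:
                continue
            got = silhouette_score(pts, labels)
            assert got == pytest.approx(brute_force_silhouette(pts, labels), abs=1e-9)

    def test_component_count_selection(self, rng):
        three = np.concatenate([rng.normal(m, 0.03, 40) for m in (-0.6, 0.0, 0.6)])
        assert select_component_count(three).k == 3
        two = np.concatenate([rng.normal(m, 0.03, 40) for m in (-0.6, 0.6)])
        assert select_component_count(two).k == 2
        one = rng.normal(0.0, 0.03, 60)
        assert select_component_count(one).k == 1

    def test_two_cluster_selection_matches_oracle_comparison(self, rng):
        x = np.concatenate([rng.normal(-0.5, 0.05, 30), rng.normal(0.5, 0.05, 30)])
        fits = {k: fit_contrast_mixture(x, k) for k in (2, 3)}
        sils = {}
        for k, fit in fits.items():
            labels = fit.hard_labels()
            if len(np.unique(labels)) >= 2:
                sils[k] = brute_force_silhouette(x, labels)
        best = max(sils, key=sils.get)
        assert select_component_count(x).k == best


class TestAssignment:
    def test_saturated_posteriors_all_assigned(self):
        x = np.array([-0.6] * 5 + [0.6] * 5)
        fit = fit_contrast_mixture(x, 2)
        assert (initial_assignment(fit) != -1).all()

    def test_below_threshold_left_unassigned(self):
        fit = fit_contrast_mixture(np.concatenate([np.full(5, -0.6), np.full(5, 0.6), [0.0]]), 2)
        # the midpoint sample has ambiguous posteriors -> unassigned
        assert initial_assignment(fit)[-1] == -1

    def test_seven_sample_hand_enumerated_medians(self):
        from vinotyper.calling import MixtureFit

        post = np.array(
            [
                [0.99, 0.01],
                [0.97, 0.03],
                [0.90, 0.10],
                [0.60, 0.40],
                [0.10, 0.90],
                [0.05, 0.95],
                [0.45, 0.55],
            ]
        )
        fit = MixtureFit(2, np.array([-0.5, 0.5]), np.ones(2), np.full(2, 0.5), post, np.zeros(1))
        # group 0 confident: rows 0-3 (other-post < 0.5); median of {.99,.97,.90,.60} = .935
        # group 1 confident: rows 4,5,6; median of {.90,.95,.55} = .90
        got = initial_assignment(fit)
        assert list(got) == [0, 0, -1, -1, 1, 1, -1]


class TestFriendsOfFriends:
    def test_identity_when_all_assigned(self):
        pts = np.random.default_rng(0).normal(0, 1, (6, 2))
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert (friends_of_friends_assign(pts, labels) == labels).all()

    def test_equidistant_tie_joins_lower_indexed_neighbor(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        labels = np.array([0, 1, -1])
        got = friends_of_friends_assign(pts, labels, scales=[1.0, 1.0])
        assert got[2] == 0

    def test_requires_an_assigned_sample(self):
        with pytest.raises(ValueError, match="at least one assigned"):
            friends_of_friends_assign(np.zeros((3, 2)), np.full(3, -1))

    def test_fuzz_matches_brute_force_accretion(self, rng):
        for _ in range(120):
            n = int(rng.integers(3, 15))
            pts = np.round(rng.normal(0, 1, (n, 2)), 3)
            labels = rng.integers(-1, 3, n)
            if not (labels != -1).any():
                labels[0] = 0
            scales = pts.std(axis=0)
            scales = np.where(scales > 0, scales, 1.0)
            got = friends_of_friends_assign(pts, labels.copy(), scales)
            expected = brute_force_accretion(pts, labels.copy(), scales)
            assert (got == expected).all()


class TestBiweight:
    def test_symmetric_sample_close_to_mean(self, rng):
        x = rng.normal(5.0, 1.0, 500)
        loc, scale = biweight_location_scale(x)
        assert loc == pytest.approx(x.mean(), abs=0.05)
        assert scale == pytest.approx(1.0, abs=0.2)

    def test_gross_outlier_rejected(self):
        loc, _ = biweight_location_scale(np.array([0.0, 0.0, 0.0, 0.0, 100.0]))
        assert loc == pytest.approx(0.0, abs=1e-9)

    def test_worked_example_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 50.0])
        got = biweight_location_scale(x, c=5.0)
        expected = brute_force_biweight(x, c=5.0)
        assert got == pytest.approx(expected)

    def test_fuzz_matches_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 30))
            x = np.round(rng.normal(0, rng.uniform(0.1, 5), n), 3)
            got = biweight_location_scale(x)
            expected = brute_force_biweight(x)
            assert got[0] == pytest.approx(expected[0], abs=1e-9)
            assert got[1] == pytest.approx(expected[1], abs=1e-9)


class TestConfidence:
    def test_center_has_confidence_one_and_boundary(self):
        from vinotyper.calling import GroupStats

        stats = GroupStats(
            centers={"A": np.array([0.5, 11.0])},
            scatters={"A": np.eye(2)},
            counts={"A": 10},
        )
        pts = np.array([[0.5, 11.0]])
        calls, conf = confidence_scores(pts, np.array(["A"], dtype=object), stats)
        assert conf[0] == pytest.approx(1.0)
        # unassignment boundary: conf 0.005 at d^2 = -2 ln 0.005
        d2 = -2 * np.log(0.005)
        assert d2 == pytest.approx(10.5966, abs=1e-4)
        pts = np.array([[0.5 + np.sqrt(d2), 11.0]])
        _, conf = confidence_scores(pts, np.array(["A"], dtype=object), stats)
        assert conf[0] == pytest.approx(0.005, rel=1e-9)

    def test_confidence_equals_chi2_survival(self, rng):
        from scipy.stats import chi2

        d2 = rng.uniform(0, 20, 100)
        np.testing.assert_allclose(np.exp(-d2 / 2), chi2.sf(d2, df=2), rtol=1e-12)


# ---------------------------------------------------------------------------
# end-to-end calling properties


def _call(intensities, **params):
    caller = GenotypeCaller(CallingParams(**params)) if params else GenotypeCaller()
    return caller.fit(intensities)


class TestCallGenotypes:
    def test_zero_noise_recovers_truth_exactly(self):
        cfg = noiseless_config(n_probes=8, n_samples=24)
        _, truth, inten = simulate_dataset(cfg)
        caller = _call(inten)
        assert (caller.calls_.to_numpy() == truth.genotypes.to_numpy()).all()

    def test_inbred_only_simulation_has_no_het_calls(self):
        cfg = SimulationConfig(n_probes=40, n_samples=60, seed=5, het_sample_fraction=0.0, otv_probe_rate=0.0)
        _, truth, inten = simulate_dataset(cfg)
        caller = _call(inten)
        ab_rate = (caller.calls_.to_numpy() == "H").mean()
        assert ab_rate <= 0.005

    def test_ab_swap_maps_aa_to_bb(self, clean_dataset):
        _, _, truth, inten = clean_dataset
        sub = inten.values.iloc[: 4 * 10]  # 10 probes
        swapped = sub.copy()
        idx = sub.index
        a_rows = idx.get_level_values("allele") == "A"
        swapped.loc[a_rows] = sub.loc[~a_rows].to_numpy()
        swapped.loc[~a_rows] = sub.loc[a_rows].to_numpy()
        c1 = _call(IntensityTable(sub)).calls_.to_numpy()
        c2 = _call(IntensityTable(swapped)).calls_.to_numpy()
        remap = {"A": "B", "B": "A", "H": "H", "N": "N"}
        assert (np.vectorize(remap.get)(c1) == c2).all()

    def test_sample_permutation_equivariance(self, clean_dataset):
        _, _, truth, inten = clean_dataset
        sub = IntensityTable(inten.values.iloc[: 4 * 8])
        perm = np.random.default_rng(3).permutation(len(sub.sample_ids))
        permuted = IntensityTable(sub.values.iloc[:, perm])
        c1 = _call(sub).calls_
        c2 = _call(permuted).calls_
        assert (c1.iloc[:, perm].to_numpy() == c2.to_numpy()).all()

    def test_zero_confidence_threshold_leaves_no_n(self, clean_dataset):
        _, _, truth, inten = clean_dataset
        sub = IntensityTable(inten.values.iloc[: 4 * 15])
        caller = _call(sub, confidence_threshold=0.0)
        assert not (caller.calls_.to_numpy() == "N").any()

    def test_label_components_k2_band_mapping(self):
        from vinotyper.calling import MixtureFit

        def fit_with_means(means):
            k = len(means)
            return MixtureFit(k, np.array(means), np.ones(k), np.full(k, 1 / k), np.zeros((1, k)), np.zeros(1))

        assert label_components(fit_with_means([-0.7, 0.7])) == ["B", "A"]
        assert label_components(fit_with_means([-0.05, 0.7])) == ["H", "A"]
        assert label_components(fit_with_means([-0.7, 0.1])) == ["B", "H"]
        assert label_components(fit_with_means([-0.8, 0.0, 0.8])) == ["B", "H", "A"]
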