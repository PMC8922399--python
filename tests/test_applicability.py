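import numpy as np
import pytest

from mtqsar.applicability import (ADModel, classify, domain_threshold, fit_ad,
                                  load_ad, pairwise_distances, save_ad, sweep)


def _toy_ad(fps, Z=-0.25, k=1, kind="euclidean_normalized"):
    """Build an ADModel directly from hand-made fingerprints."""
    dist = pairwise_distances(fps, fps, kind=kind)
    np.fill_diagonal(dist, np.inf)
    nearest = dist.min(axis=1)
    d_ave, theta = float(nearest.mean()), float(nearest.std())
    return ADModel(training_fingerprints=fps, d_ave=d_ave, theta=theta,
                   Z=Z, k=k, D_T=domain_threshold(d_ave, theta, Z),
                   distance_kind=kind, n_bits=fps.shape[1])


class TestThresholdArithmetic:
    def test_table_values_reproduced_to_four_significant_figures(self):
        d_ave, theta = 0.1262, 0.2522
        expect = {-0.25: 0.06315, -0.2: 0.07576, -0.15: 0.08837, -0.1: 0.1010}
        for z, d_t in expect.items():
            got = domain_threshold(d_ave, theta, z)
            assert float(f"{got:.4g}") == pytest.approx(d_t)

    def test_linear_in_z_with_slope_theta(self):
        rng = np.random.default_rng(0)
        d_ave, theta = rng.uniform(0, 1), rng.uniform(0, 1)
        zs = np.linspace(-2, 2, 9)
        vals = np.array([domain_threshold(d_ave, theta, z) for z in zs])
        slopes = np.diff(vals) / np.diff(zs)
        assert np.allclose(slopes, theta)


class TestFit:
    def test_identical_molecules_give_zero_stats(self):
        ad = fit_ad(["CCO", "OCC"], Z=1.5)
        assert ad.d_ave == 0.0 and ad.theta == 0.0 and ad.D_T == 0.0

    def test_hand_built_fingerprints_match_exhaustive_pairwise(self):
        fps = np.array([[1, 0, 0, 1, 0, 0, 1, 1],
                        [1, 1, 0, 1, 0, 0, 1, 0],
                        [0, 0, 1, 0, 1, 1, 0, 0],
                        [1, 0, 0, 1, 0, 0, 1, 0],
                        [0, 1, 1, 0, 1, 1, 0, 1]], dtype=np.uint8)
        ad = _toy_ad(fps, kind="euclidean_normalized")
        nearest = []
        for i in range(5):
            ds = [np.sqrt(((fps[i].astype(float) - fps[j]) ** 2).sum()) / np.sqrt(8)
                  for j in range(5) if j != i]
            nearest.append(min(ds))
        assert ad.d_ave == pytest.approx(np.mean(nearest))
        assert ad.theta == pytest.approx(np.std(nearest))

    def test_nearest_distances_match_brute_force_on_molecules(self):
        from mtqsar.synthetic import FixtureSpec, generate_library
        from mtqsar.evaluation import morgan_fingerprints
        smiles = generate_library(FixtureSpec(n_molecules=50, seed=3))
        ad = fit_ad(smiles, k=1)
        fps = morgan_fingerprints(smiles, n_bits=ad.n_bits).astype(float)
        nearest = []
        for i in range(50):
            best = np.inf
            for j in range(50):
                if i == j:
                    continue
                inter = float(fps[i] @ fps[j])
                union = fps[i].sum() + fps[j].sum() - inter
                best = min(best, 1.0 - inter / union)
            nearest.append(best)
        assert ad.d_ave == pytest.approx(np.mean(nearest), abs=1e-12)
        assert ad.theta == pytest.approx(np.std(nearest), abs=1e-12)

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError):
            fit_ad(["CCO"])


class TestClassify:
    def test_training_compound_is_in_domain(self):
        from mtqsar.synthetic import FixtureSpec, generate_library
        smiles = generate_library(FixtureSpec(n_molecules=20, seed=1))
        ad = fit_ad(smiles, Z=0.0, k=1)
        assert classify(smiles[0], ad).in_domain

    def test_negative_threshold_puts_everything_outside(self):
        ad = fit_ad(["CCO", "CCN", "c1ccccc1"], Z=-100.0, k=1)
        assert ad.D_T < 0
        assert not classify("CCO", ad).in_domain

    def test_kth_neighbor_decides(self):
        from mtqsar.applicability import classify_fingerprint
        # query at distance 0/small to two training rows, far from the third
        fps = np.array([[1, 1, 0, 0, 0, 0, 0, 0],
                        [1, 1, 0, 0, 0, 0, 1, 0],
                        [0, 0, 1, 1, 1, 1, 0, 1]], dtype=np.uint8)
        ad = _toy_ad(fps, k=3)
        ad.D_T = 0.5
        d = np.sort(pairwise_distances(fps[0][None, :], fps,
                                       "euclidean_normalized")[0])
        assert d[1] <= 0.5 < d[2]
        assert not classify_fingerprint(fps[0], ad).in_domain
        ad.k = 2
        assert classify_fingerprint(fps[0], ad).in_domain

    def test_k_larger_than_training_rejected(self):
        ad = fit_ad(["CCO", "CCN"], k=5)
        with pytest.raises(ValueError):
            classify("CCO", ad)

    def test_monotone_in_k(self):
        """in_domain at k implies in_domain at every smaller k."""
        from mtqsar.synthetic import FixtureSpec, generate_library
        smiles = generate_library(FixtureSpec(n_molecules=30, seed=2))
        queries = generate_library(FixtureSpec(n_molecules=10, seed=99))
        ad = fit_ad(smiles, Z=0.5, k=1)
        for q in queries:
            verdicts = []
            for k in (1, 2, 3, 4):
                ad.k = k
                verdicts.append(classify(q, ad).in_domain)
            for small, big in zip(verdicts, verdicts[1:]):
                assert small or not big


class TestSweep:
    def test_counts_monotone_in_z_and_k(self):
        from mtqsar.synthetic import FixtureSpec, generate_library
        train = generate_library(FixtureSpec(n_molecules=40, seed=4))
        test = generate_library(FixtureSpec(n_molecules=20, seed=5))
        ad = fit_ad(train)
        table, _ = sweep(test, ad, k_values=[3, 4, 5],
                         Z_values=[-0.25, -0.2, -0.15, -0.1])
        assert len(table) == 12
        for k in (3, 4, 5):   # larger Z -> larger D_T -> fewer OD
            sub = table[table["k"] == k].sort_values("Z")
            assert (sub["n_OD"].diff().dropna() <= 0).all()
        for z in (-0.25, -0.2, -0.15, -0.1):   # smaller k -> fewer OD
            sub = table[table["Z"] == z].sort_values("k")
            assert (sub["n_OD"].diff().dropna() >= 0).all()

    def test_single_molecule_rows_are_zero_or_one(self):
        ad = fit_ad(["CCO", "CCN", "CCC", "c1ccccc1"])
        table, _ = sweep(["CCO"], ad, [1, 2], [-0.25, 0.5])
        assert set(table["n_OD"]) <= {0, 1}

    def test_empty_grid_rejected(self):
        ad = fit_ad(["CCO", "CCN"])
        with pytest.raises(ValueError):
            sweep(["CCO"], ad, [], [-0.25])


def test_serialization_round_trip(tmp_path):
    ad = fit_ad(["CCO", "CCN", "c1ccccc1"], Z=-0.2, k=2)
    path = str(tmp_path / "ad.json")
    save_ad(ad, path)
    loaded = load_ad(path)
    assert loaded.d_ave == ad.d_ave and loaded.D_T == ad.D_T
    assert np.array_equal(loaded.training_fingerprints,
                          ad.training_fingerprints)
    assert classify("CCO", loaded).in_domain == classify("CCO", ad).in_domain
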