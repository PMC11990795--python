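import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirboost import (
    SimConfig,
    UVEConfig,
    simulate,
    tier_partition,
    uve_repeat,
    uve_run,
    zscore_fit_transform,
)
from nirboost.errors import FitError
from nirboost.uve import FrequencyProfile


def test_planted_column_recovered(rng):
    n = 60
    signal = rng.normal(size=n)
    y = signal + 0.14 * rng.normal(size=n)  # corr ~ 0.99
    X = np.column_stack([signal, rng.normal(size=(n, 100))])
    X, _ = zscore_fit_transform(X)
    run = uve_run(X, y, UVEConfig(), run_seed=0, n_lv=2)
    assert run.selected[0]


def test_null_false_positive_rate():
    import warnings

    fractions = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 80))
        y = rng.normal(size=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # "eliminated every variable" ok
            run = uve_run(X, y, UVEConfig(), run_seed=1000 + seed, n_lv=2)
        fractions.append(run.selected.mean())
    assert np.mean(fractions) <= 0.03


def test_run_determinism(rng):
    X = rng.normal(size=(40, 30))
    y = X[:, 0] + rng.normal(size=40) * 0.5
    a = uve_run(X, y, UVEConfig(), run_seed=5, n_lv=2)
    b = uve_run(X, y, UVEConfig(), run_seed=5, n_lv=2)
    assert np.array_equal(a.stability, b.stability)
    assert np.array_equal(a.selected, b.selected)
    assert a.cutoff == b.cutoff


def test_selected_mask_matches_cutoff(rng):
    X = rng.normal(size=(40, 30))
    y = X[:, 0] + rng.normal(size=40) * 0.5
    run = uve_run(X, y, UVEConfig(), run_seed=5, n_lv=2)
    assert np.array_equal(run.selected, np.abs(run.stability) > run.cutoff)
    assert run.noise_stability.size == 200


def test_confidence_nesting(rng):
    # same seed => same noise draw and folds; only the cutoff moves
    X = rng.normal(size=(50, 40))
    y = X[:, 0] + rng.normal(size=50) * 0.5
    strict = uve_run(X, y, UVEConfig(confidence=0.99), run_seed=3, n_lv=2)
    loose = uve_run(X, y, UVEConfig(confidence=0.95), run_seed=3, n_lv=2)
    assert np.array_equal(strict.stability, loose.stability)
    assert strict.cutoff >= loose.cutoff
    assert np.all(loose.selected[strict.selected])  # strict subset of loose


def test_cutoff_depends_only_on_noise(rng):
    # swapping the real block for fresh noise leaves the cutoff distribution
    # centred in the same place (same seed => same appended noise columns)
    y = rng.normal(size=50)
    cutoffs = []
    for block_seed in (1, 2):
        X = np.random.default_rng(block_seed).normal(size=(50, 40))
        run = uve_run(X, y, UVEConfig(), run_seed=9, n_lv=2)
        cutoffs.append(run.cutoff)
    # not bitwise equal (fits differ) but same order of magnitude
    assert 0.2 < cutoffs[0] / cutoffs[1] < 5.0


class TestUVERepeat:
    def test_single_run_counts(self, rng):
        X = rng.normal(size=(40, 25))
        y = X[:, 0] + rng.normal(size=40) * 0.3
        config = UVEConfig(n_runs=1, seed=4)
        runs, profile = uve_repeat(X, y, config, n_lv=2)
        assert len(runs) == 1
        assert np.array_equal(profile.counts, runs[0].selected.astype(int))

    def test_counts_conservation(self, rng):
        X = rng.normal(size=(40, 25))
        y = X[:, 0] + rng.normal(size=40) * 0.3
        runs, profile = uve_repeat(X, y, UVEConfig(n_runs=10, seed=4), n_lv=2)
        union = np.any([r.selected for r in runs], axis=0)
        assert (profile.counts >= 1).sum() == union.sum()
        assert profile.counts.max() <= 10

    def test_repeat_determinism(self, rng):
        X = rng.normal(size=(40, 25))
        y = X[:, 0] + rng.normal(size=40) * 0.3
        _, p1 = uve_repeat(X, y, UVEConfig(n_runs=5, seed=4), n_lv=2)
        _, p2 = uve_repeat(X, y, UVEConfig(n_runs=5, seed=4), n_lv=2)
        assert np.array_equal(p1.counts, p2.counts)

    def test_band_recovery_small(self):
        # scaled-down version of the frequency-recovery protocol
        ds, truth = simulate(SimConfig(n_samples=120, n_points=200, seed=11))
        X, _ = zscore_fit_transform(ds.X)
        config = UVEConfig(n_runs=30, seed=2, t_high=27, t_low=9)
        _, profile = uve_repeat(X, ds.y, config)
        high, _, _ = tier_partition(profile)
        truth_set = set(truth.informative_indices.tolist())
        high_set = set(high.tolist())
        precision = len(high_set & truth_set) / max(len(high_set), 1)
        recall = len(high_set & truth_set) / len(truth_set)
        assert precision >= 0.7 and recall >= 0.7


class TestTierPartition:
    def test_boundary_semantics(self):
        profile = FrequencyProfile(
            counts=np.array([95, 90, 89, 30, 29, 0]), n_runs=100
        )
        high, mid, low = tier_partition(profile)
        assert high.tolist() == [0, 1]
        assert mid.tolist() == [2, 3]
        assert low.tolist() == [4]
        assert profile.tiers.tolist() == [
            "high", "high", "mid", "mid", "low", "never"
        ]

    def test_all_max_counts(self):
        profile = FrequencyProfile(counts=np.full(7, 100), n_runs=100)
        high, mid, low = tier_partition(profile)
        assert high.size == 7 and mid.size == 0 and low.size == 0

    def test_empty_high_warns(self):
        profile = FrequencyProfile(counts=np.array([50, 10]), n_runs=100)
        with pytest.warns(UserWarning, match="high"):
            tier_partition(profile)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=40))
    def test_tiers_disjoint_and_cover(self, counts):
        profile = FrequencyProfile(counts=np.array(counts), n_runs=100)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            high, mid, low = tier_partition(profile)
        combined = np.concatenate([high, mid, low])
        assert len(combined) == len(set(combined.tolist()))
        assert set(combined.tolist()) == set(
            np.flatnonzero(profile.counts >= 1).tolist()
        )


def test_config_validation():
    with pytest.raises(FitError):
        UVEConfig(n_noise=5)
    with pytest.raises(FitError):
        UVEConfig(confidence=0.4)
    with pytest.raises(FitError):
        UVEConfig(n_runs=0)
    with pytest.raises(FitError):
        UVEConfig(noise_distribution="poisson")


def test_too_few_samples(rng):
    X = rng.normal(size=(3, 10))
    with pytest.raises(FitError, match="k_folds"):
        uve_run(X, rng.normal(size=3), UVEConfig(), run_seed=0, n_lv=1)
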