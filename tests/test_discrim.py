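import numpy as np
import pytest
from scipy.stats import kstest

from netstab.cohort import REFERENCE_SIM, SampleKey
from netstab.discrim import (
    HYPOTHESIS_COMPARISONS,
    compare_conditions,
    count_tests,
    default_scaled_score,
    discriminability,
    permutation_test,
    run_hypothesis,
)


def brute_force_discriminability(x, labels):
    """Independent O(n^3) oracle: enumerate every triple explicitly."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    hits = total = 0
    for i in range(n):
        for j in range(n):
            if j == i or labels[j] != labels[i]:
                continue
            for k in range(n):
                if labels[k] == labels[i]:
                    continue
                total += 1
                if dist[i, j] <= dist[i, k]:
                    hits += 1
    return hits / total


class TestDiscriminability:
    def test_perfect_separation(self):
        x = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 10])
        labels = [0, 0, 0, 1, 1, 1]
        assert discriminability(x, labels) == 1.0

    def test_hand_enumerable_eight_triples(self):
        # 4 observations, 2 classes of 2: each anchor has 1 within partner
        # and 2 cross observations -> 4 * 1 * 2 = 8 triples
        x = np.array([[0.0], [1.0], [5.0], [5.5]])
        labels = [0, 0, 1, 1]
        expected = brute_force_discriminability(x, labels)
        assert discriminability(x, labels) == pytest.approx(expected)
        # verified by hand: all 8 triples succeed
        assert expected == 1.0

    def test_partial_overlap_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(6, 30))
            n_classes = int(rng.integers(2, 4))
            labels = np.repeat(np.arange(n_classes), 2)
            labels = np.concatenate(
                [labels, rng.integers(0, n_classes, size=max(0, n - len(labels)))]
            )
            x = rng.normal(size=(len(labels), 3)) + labels[:, None]
            assert discriminability(x, labels) == pytest.approx(
                brute_force_discriminability(x, labels)
            )

    def test_exchangeable_null_centers_on_half(self):
        """Monte Carlo null oracle: exchangeable 2-class data has D = 0.5."""
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(100, 4))
            labels = np.repeat([0, 1], 50)
            vals.append(discriminability(x, labels))
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - 0.5) < 3 * se + 1e-12

    def test_singleton_class_rejected(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError):
            discriminability(x, [0, 0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discriminability(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_rank_invariance_under_monotone_distance_transform(self):
        # squared euclidean is a strictly increasing transform of euclidean
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        labels = np.repeat([0, 1, 2], 4)
        d1 = discriminability(x, labels, metric="euclidean")
        d2 = discriminability(x, labels, metric="sqeuclidean")
        assert d1 == pytest.approx(d2)

    def test_relabeling_and_order_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 2))
        labels = np.repeat([0, 1], 5)
        d = discriminability(x, labels)
        # relabel classes
        assert discriminability(x, 1 - labels) == pytest.approx(d)
        # permute observation order
        perm = rng.permutation(10)
        assert discriminability(x[perm], labels[perm]) == pytest.approx(d)

    def test_duplicates_never_decrease(self):
        """Duplicated within-class observations tie at distance zero and
        count as successes, so D cannot decrease."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 2))
        labels = np.repeat([0, 1], 4)
        d = discriminability(x, labels)
        x2 = np.vstack([x, x[:4]])
        labels2 = np.concatenate([labels, labels[:4]])
        assert discriminability(x2, labels2) >= d - 1e-12


class TestPermutationTest:
    def test_strong_separation_minimum_p(self):
        x = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 50])
        labels = np.repeat([0, 1], 10)
        # seed chosen so no permutation reproduces the class partition
        # (a coinciding permutation ties at D = 1 and is counted, by design)
        p, d = permutation_test(x, labels, n_perm=999, seed=1)
        assert d == 1.0
        assert p == pytest.approx(1.0 / 1000.0)

    def test_observed_below_null_gives_one(self):
        # interleaved classes: within-class distances are maximal
        x = np.array([[0.0], [2.0], [1.0], [3.0]])
        labels = [0, 0, 1, 1]
        d = discriminability(x, labels)
        p, d_obs, null = permutation_test(
            x, labels, n_perm=200, seed=0, return_null=True
        )
        if np.all(null >= d):
            assert p == 1.0

    def test_null_calibration_uniform(self):
        """Under label independence the p-value is uniform on the
        permutation grid (KS check over 200 repetitions)."""
        pvals = []
        n_perm = 99
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(size=(12, 3))
            labels = np.repeat([0, 1], 6)
            p, _ = permutation_test(x, labels, n_perm=n_perm, seed=rep)
            pvals.append(p)
        stat = kstest(pvals, "uniform").statistic
        # allow the half-grid-spacing offset of the discrete null
        assert stat < 0.12

    def test_block_permutation_respects_blocks(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 2))
        labels = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        blocks = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        p, _ = permutation_test(x, labels, blocks=blocks, n_perm=50, seed=0)
        assert 0 < p <= 1

    def test_n_perm_validated(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((4, 1)), [0, 0, 1, 1], n_perm=0)


def _cohort_connectomes(
    n_subjects=5, n_sessions=2, n_subsamples=2, n_sims=3,
    separation=1.0, mca_noise=1e-3, seed=0, modes=("dense",),
    mode_noise=None,
):
    """Synthetic connectome vectors arranged as a keyed cohort."""
    rng = np.random.default_rng(seed)
    n_nodes = 6
    conns = {}
    for subj in range(n_subjects):
        base = rng.normal(size=(n_nodes, n_nodes)) * separation
        base = np.triu(base, 1) + np.triu(base, 1).T
        for ses in range(n_sessions):
            ses_eff = rng.normal(size=(n_nodes, n_nodes)) * 0.3
            ses_eff = np.triu(ses_eff, 1) + np.triu(ses_eff, 1).T
            for sub in range(n_subsamples):
                sub_eff = rng.normal(size=(n_nodes, n_nodes)) * 0.1
                sub_eff = np.triu(sub_eff, 1) + np.triu(sub_eff, 1).T
                mean = base + ses_eff + sub_eff
                for mode in modes:
                    noise_scale = (
                        mca_noise if mode_noise is None else mode_noise[mode]
                    )
                    key = SampleKey(subj, ses, sub, "det-like", mode, REFERENCE_SIM)
                    conns[key] = np.abs(mean)
                    for sim in range(n_sims):
                        nz = rng.normal(size=(n_nodes, n_nodes)) * noise_scale
                        nz = np.triu(nz, 1) + np.triu(nz, 1).T
                        conns[SampleKey(subj, ses, sub, "det-like", mode, sim)] = (
                            np.abs(mean + nz)
                        )
    return conns


class TestRunHypothesis:
    def test_h1_chance_level(self):
        conns = _cohort_connectomes(n_subjects=25, n_sims=2)
        res = run_hypothesis(conns, "H1", "det-like", "dense",
                             comparison="session", n_perm=20, seed=0)
        assert res.chance == pytest.approx(1.0 / 25.0)
        assert res.chance == pytest.approx(0.04)

    def test_h2_h3_chance_level(self):
        conns = _cohort_connectomes(n_subjects=4, n_sims=3)
        for hyp in ("H2", "H3"):
            res = run_hypothesis(conns, hyp, "det-like", "dense",
                                 comparison=HYPOTHESIS_COMPARISONS[hyp][-1],
                                 n_perm=20, seed=0)
            assert res.n_classes == 2
            assert res.chance == 0.5

    def test_h3_requires_perturbed_runs(self):
        conns = {
            k: v for k, v in _cohort_connectomes(n_sims=0).items()
            if k.sim == REFERENCE_SIM
        }
        with pytest.raises(ValueError):
            run_hypothesis(conns, "H3", "det-like", "dense", n_perm=10)

    def test_h3_reference_comparison_unsupported(self):
        conns = _cohort_connectomes()
        with pytest.raises(ValueError):
            run_hypothesis(conns, "H3", "det-like", "dense",
                           comparison="session", n_perm=10)

    def test_strong_structure_significant(self):
        conns = _cohort_connectomes(n_subjects=6, separation=3.0, mca_noise=1e-4)
        res = run_hypothesis(conns, "H1", "det-like", "dense",
                             comparison="mca", n_perm=99, seed=1)
        assert res.statistic > 0.9
        assert res.p_value < 0.05
        assert 0 <= res.scaled_score <= 1.0 + 1e-12

    def test_low_noise_mode_not_less_discriminable(self):
        """With nested instrumentation the lower-noise arm cannot have
        lower session discriminability (see ledger on the source study's
        non-nested finding)."""
        conns = _cohort_connectomes(
            modes=("dense", "sparse"),
            mode_noise={"dense": 0.3, "sparse": 0.05},
            n_subjects=5, n_sims=4, seed=6,
        )
        res = {
            m: run_hypothesis(conns, "H2", "det-like", m,
                              comparison="mca", n_perm=20, seed=2)
            for m in ("dense", "sparse")
        }
        assert res["sparse"].statistic >= res["dense"].statistic - 0.05

    def test_scaled_score_hook(self):
        conns = _cohort_connectomes(n_subjects=4)
        res = run_hypothesis(
            conns, "H2", "det-like", "dense", comparison="mca",
            n_perm=20, seed=0, scale_fn=lambda d, c: 42.0,
        )
        assert res.scaled_score == 42.0

    def test_default_scaled_score(self):
        assert default_scaled_score(1.0, 0.5) == 1.0
        assert default_scaled_score(0.5, 0.5) == 0.0
        assert default_scaled_score(0.75, 0.5) == 0.5


class TestCompareConditions:
    def test_identical_lists_degenerate(self):
        a = [0.5, 0.6, 0.7]
        df = compare_conditions(a, list(a))
        assert bool(df["degenerate"].iloc[0])
        assert not bool(df["reject"].iloc[0])

    def test_shifted_list_strongly_significant(self):
        # n = 20 constant +1 shift: signed-rank p well below 1e-3
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        b = a + 1.0
        df = compare_conditions(a, b)
        assert df["p_corrected"].iloc[0] < 1e-3
        assert df["direction"].iloc[0] == 1.0

    def test_bh_false_rejections_bounded(self):
        """Simulation oracle: 10 true-null comparisons under BH reject
        about alpha * 10 or fewer on average."""
        rng = np.random.default_rng(7)
        rejections = []
        for _ in range(100):
            pairs = []
            for _ in range(10):
                a = rng.normal(size=20)
                b = a + rng.normal(size=20) * 0.5
                pairs.append((a, b))
            df = compare_conditions(*pairs[0], *pairs[1:])
            rejections.append(int(df["reject"].sum()))
        mean_rej = np.mean(rejections)
        se = np.std(rejections, ddof=1) / 10.0
        assert mean_rej <= 0.05 * 10 + 3 * se

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0, 2.0], [1.0])


class TestCountTests:
    def test_paper_grid_thirty(self):
        assert count_tests() == 30

    def test_empty_grid(self):
        assert count_tests({}, n_pipelines=2, n_modes=2) == 0

    def test_single_cell(self):
        assert count_tests({"H3": ("mca",)}, n_pipelines=1, n_modes=1) == 1
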