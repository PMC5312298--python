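"""Signature folding, KL-NMF, consensus clustering and subtype labeling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rmpa.data_io import ExpressionMatrix
from rmpa.module_discovery import CoexpressionModule
from rmpa.rmpa_classifier import (
    LABEL_HIGH,
    LABEL_LOW,
    SignatureMatrix,
    build_signature_matrix,
    classify,
    consensus_cluster,
    cophenetic_coefficient,
    hierarchical_split,
    label_subtypes,
    nmf_run,
    rmpa_score,
)
from rmpa.synthetic_cohort import CohortConfig, generate, truth_agreement


def _module(name, genes):
    return CoexpressionModule(name, [], set(), set(genes), len(genes), set())


def _expr(rows: dict[str, list[float]], samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# signature matrix
# ---------------------------------------------------------------------------

class TestSignatureMatrix:
    def test_signed_folding(self):
        expr = _expr({"gA": [1.0, -1.0, 0.0], "gB": [0.5, 0.2, 0.1]})
        sig = build_signature_matrix(expr, [_module("SPRY-M", ["gA", "gB"])],
                                     standardize=False)
        assert sig.values.loc["gA|pos"].tolist() == [1.0, 0.0, 0.0]
        assert sig.values.loc["gA|neg"].tolist() == [0.0, 1.0, 0.0]

    def test_pos_neg_product_is_zero(self, small_cohort):
        sig = build_signature_matrix(
            small_cohort.expression, small_cohort.truth.modules()
        )
        arr = sig.values.to_numpy()
        assert (arr >= 0).all()
        assert np.allclose(arr[0::2] * arr[1::2], 0.0)

    def test_constant_gene_excluded(self):
        expr = _expr({"gA": [1.0, 2.0, 3.0], "gB": [1.0, 1.0, 1.0],
                      "gC": [0.0, 1.0, 2.0]})
        sig = build_signature_matrix(expr, [_module("SPRY-M", ["gA", "gB", "gC"])])
        assert not any(r.startswith("gB|") for r in sig.values.index)

    def test_row_count_is_twice_gene_count(self):
        cohort = generate(CohortConfig(
            n_samples=30, module_sizes={"SPRY-M": 10, "NF1-M": 10, "PTEN-M": 10},
            n_background_genes=5, seed=0))
        sig = build_signature_matrix(cohort.expression, cohort.truth.modules())
        assert sig.values.shape[0] == 60

    def test_too_few_genes_rejected(self):
        expr = _expr({"gA": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            build_signature_matrix(expr, [_module("SPRY-M", ["gA"])])


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

class TestNMF:
    def test_rank_one_matrix_factorizes_exactly(self):
        rng = np.random.default_rng(0)
        V = np.outer(rng.uniform(0.5, 2, 12), rng.uniform(0.5, 2, 8))
        fact = nmf_run(V, k=1, seed=1, max_iter=5000, tol=1e-12)
        assert fact.objective_trace[-1] < 1e-8

    def test_same_seed_identical_factors(self):
        rng = np.random.default_rng(3)
        V = rng.uniform(0, 1, (15, 10))
        a = nmf_run(V, k=2, seed=9)
        b = nmf_run(V, k=2, seed=9)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.uniform(0, 1, (20, 15))
        fact = nmf_run(V, k=2, seed=seed)
        diffs = np.diff(fact.objective_trace)
        scale = max(1.0, abs(fact.objective_trace[0]))
        assert (diffs <= 1e-10 * scale).all()

    def test_invalid_inputs_rejected(self):
        V = np.ones((5, 4))
        with pytest.raises(ValueError, match="smaller than the sample count"):
            nmf_run(V, k=4)
        with pytest.raises(ValueError, match="all-zero"):
            nmf_run(np.zeros((5, 4)), k=2)

    def test_matches_sklearn_mu_solver_quality(self):
        """Independent cross-check: final KL divergence is on par with
        scikit-learn's multiplicative-update KL NMF."""
        from sklearn.decomposition import NMF as SkNMF
        from rmpa.rmpa_classifier import _kl_divergence

        rng = np.random.default_rng(7)
        V = rng.uniform(0, 2, (30, 20))
        mine = nmf_run(V, k=3, seed=5, max_iter=3000, tol=1e-9)
        sk = SkNMF(n_components=3, solver="mu", beta_loss="kullback-leibler",
                   init="random", random_state=5, max_iter=3000, tol=1e-9)
        W = sk.fit_transform(V)
        sk_div = _kl_divergence(V, W @ sk.components_ + 1e-12)
        assert mine.objective_trace[-1] <= sk_div * 1.05


# ---------------------------------------------------------------------------
# consensus clustering + cophenetic coefficient
# ---------------------------------------------------------------------------

def _separated_cohort(n=24, seed=0):
    return generate(CohortConfig(
        n_samples=n, effect_delta=6.0, noise_sd=0.2,
        module_sizes={"SPRY-M": 6, "NF1-M": 6, "PTEN-M": 6},
        n_background_genes=10, seed=seed))


class TestConsensus:
    def test_perfect_blocks_give_binary_consensus(self):
        cohort = _separated_cohort()
        sig = build_signature_matrix(cohort.expression, cohort.truth.modules())
        res = consensus_cluster(sig, k_values=(2,), n_runs=10, base_seed=1)[2]
        C = res.consensus.to_numpy()
        assert set(np.round(C.ravel(), 12)) <= {0.0, 1.0}
        agree, ari = truth_agreement(
            res.labels.map({res.labels.iloc[0]: LABEL_HIGH}).fillna(LABEL_LOW),
            cohort.truth,
        )
        assert agree == 1.0

    def test_single_run_rejected(self):
        cohort = _separated_cohort()
        sig = build_signature_matrix(cohort.expression, cohort.truth.modules())
        with pytest.raises(ValueError, match="n_runs"):
            consensus_cluster(sig, k_values=(2,), n_runs=1)

    def test_sample_permutation_equivariance(self):
        cohort = _separated_cohort()
        sig = build_signature_matrix(cohort.expression, cohort.truth.modules())
        res = consensus_cluster(sig, k_values=(2,), n_runs=8, base_seed=4)[2]
        perm = np.random.default_rng(0).permutation(len(sig.sample_ids))
        sig_p = SignatureMatrix(sig.values.iloc[:, perm])
        res_p = consensus_cluster(sig_p, k_values=(2,), n_runs=8, base_seed=4)[2]
        pd.testing.assert_frame_equal(
            res.consensus.loc[sig_p.sample_ids, sig_p.sample_ids], res_p.consensus
        )


def _brute_force_cophenetic(C: np.ndarray) -> float:
    """Naive average-linkage + explicit dendrogram walk, independent of
    scipy.cluster.hierarchy."""
    n = C.shape[0]
    D = 1.0 - C
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if d < best:
                best, pair = d, (a, b)
        a, b = pair
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    iu = np.triu_indices(n, 1)
    return float(np.corrcoef(D[iu], coph[iu])[0, 1])


class TestCophenetic:
    def test_perfect_two_block_consensus_gives_one(self):
        C = np.kron(np.eye(2), np.ones((3, 3)))
        assert cophenetic_coefficient(C) == pytest.approx(1.0)

    def test_constant_offdiagonal_flagged_undefined(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        assert np.isnan(cophenetic_coefficient(C))

    def test_matches_brute_force_dendrogram_walk(self):
        """6x6 hand-built consensus vs an explicit naive oracle."""
        C = np.array([
            [1.00, 0.90, 0.75, 0.20, 0.10, 0.05],
            [0.90, 1.00, 0.70, 0.25, 0.15, 0.10],
            [0.75, 0.70, 1.00, 0.30, 0.20, 0.15],
            [0.20, 0.25, 0.30, 1.00, 0.85, 0.65],
            [0.10, 0.15, 0.20, 0.85, 1.00, 0.60],
            [0.05, 0.10, 0.15, 0.65, 0.60, 1.00],
        ])
        assert cophenetic_coefficient(C) == pytest.approx(
            _brute_force_cophenetic(C), abs=1e-12
        )

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            cophenetic_coefficient(np.eye(2))


# ---------------------------------------------------------------------------
# labeling, score, hierarchical split
# ---------------------------------------------------------------------------

def _pattern_expr(spry_a, nf1_a, pten_a):
    """6 samples: cluster A = first 3 with the given module means, B mirrored."""
    def row(mean_a, jitter):
        return [mean_a + j for j in jitter] + [-mean_a + j for j in jitter]

    jit = [0.0, 0.05, -0.05]
    rows = {}
    for i in range(2):
        rows[f"spry{i}"] = row(spry_a, jit)
        rows[f"nf1{i}"] = row(nf1_a, jit)
        rows[f"pten{i}"] = row(pten_a, jit)
    return _expr(rows)


_MODULES = [
    _module("SPRY-M", ["spry0", "spry1"]),
    _module("NF1-M", ["nf10", "nf11"]),
    _module("PTEN-M", ["pten0", "pten1"]),
]
_CLUSTERS = pd.Series([0, 0, 0, 1, 1, 1], index=[f"s{i}" for i in range(6)])


class TestLabelSubtypes:
    def test_concordant_pattern_three_votes(self):
        expr = _pattern_expr(spry_a=1.0, nf1_a=-1.0, pten_a=-1.0)
        assign = label_subtypes(_CLUSTERS, expr, _MODULES)
        assert (assign.labels[:3] == LABEL_HIGH).all()
        assert (assign.labels[3:] == LABEL_LOW).all()
        assert not assign.discordant

    def test_swapped_pattern_flips_labels(self):
        expr = _pattern_expr(spry_a=-1.0, nf1_a=1.0, pten_a=1.0)
        assign = label_subtypes(_CLUSTERS, expr, _MODULES)
        assert (assign.labels[:3] == LABEL_LOW).all()
        assert (assign.labels[3:] == LABEL_HIGH).all()

    def test_majority_vote_with_discordance_flag(self):
        expr = _pattern_expr(spry_a=1.0, nf1_a=-1.0, pten_a=0.2)
        assign = label_subtypes(_CLUSTERS, expr, _MODULES)
        assert (assign.labels[:3] == LABEL_HIGH).all()
        assert assign.discordant

    def test_requires_two_clusters(self):
        expr = _pattern_expr(1.0, -1.0, -1.0)
        with pytest.raises(ValueError, match="2 clusters"):
            label_subtypes(pd.Series(0, index=_CLUSTERS.index), expr, _MODULES)

    def test_orientation_invariant_to_cluster_relabeling(self):
        expr = _pattern_expr(1.0, -1.0, -1.0)
        flipped = _CLUSTERS.map({0: 1, 1: 0})
        a = label_subtypes(_CLUSTERS, expr, _MODULES)
        b = label_subtypes(flipped, expr, _MODULES)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestRMPAScore:
    def test_pattern_scores(self):
        # two samples at +/-1 z exactly (population sd = 1)
        expr = _expr({"spry0": [1, -1], "spry1": [1, -1],
                      "nf10": [-1, 1], "nf11": [-1, 1],
                      "pten0": [-1, 1], "pten1": [-1, 1]})
        score = rmpa_score(expr, _MODULES)
        assert score["s0"] == pytest.approx(2.0)
        assert score["s1"] == pytest.approx(-2.0)

    def test_sample_at_gene_means_scores_zero(self):
        expr = _expr({"spry0": [1, 0, -1], "spry1": [2, 0, -2],
                      "nf10": [-1, 0, 1], "nf11": [-3, 0, 3],
                      "pten0": [-1, 0, 1], "pten1": [1, 0, -1]})
        score = rmpa_score(expr, _MODULES)
        assert score["s1"] == pytest.approx(0.0)

    def test_duplicating_module_members_leaves_score_unchanged(self):
        expr = _expr({"spry0": [1, -1], "nf10": [-1, 1], "pten0": [-1, 1]})
        mods1 = [_module("SPRY-M", ["spry0"]), _module("NF1-M", ["nf10"]),
                 _module("PTEN-M", ["pten0"])]
        expr2 = _expr({"spry0": [1, -1], "spry1": [1, -1],
                       "nf10": [-1, 1], "pten0": [-1, 1]})
        mods2 = [_module("SPRY-M", ["spry0", "spry1"]), _module("NF1-M", ["nf10"]),
                 _module("PTEN-M", ["pten0"])]
        pd.testing.assert_series_equal(rmpa_score(expr, mods1),
                                       rmpa_score(expr2, mods2))

    def test_empty_module_rejected(self):
        expr = _expr({"spry0": [1, -1], "nf10": [-1, 1], "pten0": [-1, 1]})
        mods = [_module("SPRY-M", ["missing"]), _module("NF1-M", ["nf10"]),
                _module("PTEN-M", ["pten0"])]
        with pytest.raises(ValueError, match="no members"):
            rmpa_score(expr, mods)


class TestHierarchicalSplit:
    def test_recovers_two_planted_blocks(self):
        cohort = _separated_cohort(n=20, seed=3)
        split = hierarchical_split(cohort.expression, cohort.truth.modules())
        mapped = split.map({"high": LABEL_HIGH, "low": LABEL_LOW})
        assert (mapped == cohort.truth.subtype).all()

    def test_high_group_has_higher_mean_score(self):
        cohort = _separated_cohort(n=20, seed=4)
        mods = cohort.truth.modules()
        split = hierarchical_split(cohort.expression, mods)
        scores = rmpa_score(cohort.expression, mods)
        assert scores[split == "high"].mean() > scores[split == "low"].mean()

    def test_subset_argument(self):
        cohort = _separated_cohort(n=20, seed=5)
        subset = cohort.expression.sample_ids[:10]
        split = hierarchical_split(cohort.expression, cohort.truth.modules(), subset)
        assert list(split.index) == subset

    def test_too_few_samples_rejected(self):
        cohort = _separated_cohort(n=20, seed=6)
        with pytest.raises(ValueError, match=">= 4"):
            hierarchical_split(cohort.expression, cohort.truth.modules(),
                               cohort.expression.sample_ids[:3])


class TestEndToEnd:
    def test_classify_recovers_planted_subtypes(self, default_cohort):
        assign, res = classify(
            default_cohort.expression, default_cohort.truth.modules(),
            n_runs=20, seed=5,
        )
        agree, ari = truth_agreement(assign, default_cohort.truth)
        assert agree >= 0.95 and ari >= 0.8
        assert res.cophenetic > 0.95
        # orientation invariant: RMPA_high has the higher SPRY-M centroid
        assert (assign.centroids.loc["SPRY-M", LABEL_HIGH]
                > assign.centroids.loc["SPRY-M", LABEL_LOW])
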