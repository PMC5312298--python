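"""RMPA subtype classification by NMF consensus clustering.

The three-module signature (SPRY-M, NF1-M, PTEN-M member genes) is
standardized per gene and made nonnegative by signed folding: each z-scored
row splits into a positive part max(z, 0) and a negative part max(-z, 0),
so both over- and under-expression survive the nonnegativity constraint.
Samples are clustered by repeated KL-divergence multiplicative-update NMF
from random starts; co-clustering frequencies form a consensus matrix whose
average-linkage tree yields the final two clusters and the cophenetic
stability coefficient.  The cluster with high SPRY-M and low NF1-M/PTEN-M
centroids is labeled RMPA-high, its mirror RMPA-low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix
from .module_discovery import CoexpressionModule

logger = logging.getLogger("rmpa")

_EPS = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# signature construction
# ---------------------------------------------------------------------------

@dataclass
class SignatureMatrix:
    """Folded, per-gene standardized module expression (all entries >= 0).

    Each usable gene contributes a ``<gene>|pos`` and a ``<gene>|neg`` row
    whose elementwise product is zero.
    """

    values: pd.DataFrame  # rows = "<gene>|pos" / "<gene>|neg", cols = samples

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=1, keepdims=True)
    mean = arr.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        z = (arr - mean) / sd
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def _module_rows(expr: ExpressionMatrix, module: CoexpressionModule) -> list[str]:
    """Expression rows belonging to a module, matched by probe then gene id."""
    idx = expr.values.index
    by_probe = [p for p in sorted(module.member_probes) if p in idx]
    if by_probe:
        return by_probe
    return [g for g in sorted(module.member_genes) if g in idx]


def build_signature_matrix(
    expr: ExpressionMatrix,
    modules: list[CoexpressionModule],
    standardize: bool = True,
) -> SignatureMatrix:
    """Restrict to module members, z-score per gene, fold into pos/neg rows.

    Zero-variance genes are excluded (z undefined); absent members are
    logged and skipped.
    """
    rows: list[str] = []
    for m in modules:
        matched = _module_rows(expr, m)
        missing = len(m.member_probes or m.member_genes) - len(matched)
        if missing > 0:
            logger.info("signature: module %s, %d member(s) absent from matrix",
                        m.name, missing)
        rows.extend(r for r in matched if r not in rows)
    sub = expr.values.loc[rows]
    sd = sub.to_numpy().std(axis=1)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.info("signature: excluded %d zero-variance gene(s)", n_const)
        sub = sub.loc[sd > 0]
    if len(sub) < 2:
        raise ValueError("fewer than 2 usable module genes for the signature")
    z = _zscore_rows(sub) if standardize else sub
    arr = z.to_numpy(dtype=float)
    pos = np.maximum(arr, 0.0)
    neg = np.maximum(-arr, 0.0)
    stacked = np.empty((2 * len(z), arr.shape[1]))
    stacked[0::2] = pos
    stacked[1::2] = neg
    index = [f"{g}|{part}" for g in z.index for part in ("pos", "neg")]
    return SignatureMatrix(pd.DataFrame(stacked, index=index, columns=z.columns))


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

@dataclass
class Factorization:
    W: np.ndarray  # features x k
    H: np.ndarray  # k x samples
    objective_trace: np.ndarray  # KL divergence per recorded iteration
    seed: int
    n_iter: int
    converged: bool


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH)."""
    mask = V > 0
    div = float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V[mask].sum() + WH.sum())
    return div


def nmf_run(
    sig: SignatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> Factorization:
    """One KL-divergence multiplicative-update NMF from a random start.

    W and H initialize uniform(0, 1]; updates are the standard multiplicative
    rules, which keep the divergence non-increasing.  Stops when the relative
    objective change stays below ``tol`` for 10 consecutive iterations, or at
    ``max_iter``.
    """
    V = sig.values.to_numpy(dtype=float) if isinstance(sig, SignatureMatrix) else np.asarray(sig, dtype=float)
    n_feat, n_samp = V.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_samp:
        raise ValueError(f"k={k} must be smaller than the sample count {n_samp}")
    if not (V >= 0).all():
        raise ValueError("signature matrix must be nonnegative")
    if V.max() == 0:
        raise ValueError("all-zero matrix cannot be factorized")

    rng = np.random.default_rng(seed)
    # uniform (0, 1]: avoid exact zeros that freeze multiplicative updates
    W = 1.0 - rng.random((n_feat, k))
    H = 1.0 - rng.random((k, n_samp))

    trace = []
    prev = np.inf
    small_steps = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        obj = _kl_divergence(V, W @ H + _EPS)
        trace.append(obj)
        denom = abs(prev) if np.isfinite(prev) and prev != 0 else 1.0
        if np.isfinite(prev) and (prev - obj) / denom < tol:
            small_steps += 1
            if small_steps >= 10:
                converged = True
                break
        else:
            small_steps = 0
        prev = obj
    return Factorization(W, H, np.asarray(trace), seed, it, converged)


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # samples x samples, co-clustering frequency
    labels: pd.Series  # sample -> cluster index 0..k-1
    cophenetic: float  # nan when undefined
    n_runs: int


def _run_labels(fact: Factorization) -> np.ndarray:
    """Per-sample cluster: argmax row of H (ties -> lower cluster index)."""
    return np.argmax(fact.H, axis=0)


def consensus_cluster(
    sig: SignatureMatrix,
    k_values: list[int] | tuple[int, ...] = (2,),
    n_runs: int = 50,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> dict[int, ConsensusResult]:
    """Consensus NMF over random restarts, one result per k.

    Each run clusters samples by the dominant H row; connectivity matrices
    average into the consensus matrix C; final labels cut the
    average-linkage tree of 1 - C into k groups, and the cophenetic
    coefficient of that same tree measures stability.
    """
    if n_runs < 2:
        raise ValueError("consensus requires n_runs >= 2")
    samples = sig.sample_ids
    n = len(samples)
    results: dict[int, ConsensusResult] = {}
    ss = np.random.SeedSequence(base_seed)
    for k in k_values:
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
        C = np.zeros((n, n))
        for run_idx, seed in enumerate(seeds):
            try:
                fact = nmf_run(sig, k, seed=seed, max_iter=max_iter, tol=tol)
            except Exception as exc:  # surface which restart failed
                raise RuntimeError(f"NMF run {run_idx} (k={k}) failed: {exc}") from exc
            lab = _run_labels(fact)
            C += (lab[:, None] == lab[None, :]).astype(float)
        C /= n_runs
        np.fill_diagonal(C, 1.0)
        labels, rho = _cut_consensus(C, k)
        results[k] = ConsensusResult(
            k=k,
            consensus=pd.DataFrame(C, index=samples, columns=samples),
            labels=pd.Series(labels, index=samples),
            cophenetic=rho,
            n_runs=n_runs,
        )
        logger.info("consensus k=%d: cophenetic=%.4f over %d runs", k, rho, n_runs)
    return results


def _cut_consensus(C: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    dist = squareform(1.0 - C, checks=False)
    Z = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    if np.ptp(dist) == 0:
        return labels, np.nan
    rho, _ = hierarchy.cophenet(Z, dist)
    return labels, float(rho)


def cophenetic_coefficient(C: pd.DataFrame | np.ndarray) -> float:
    """Stability of a consensus matrix: correlation between 1 - C distances
    and the cophenetic distances of their average-linkage tree.

    Returns nan (flagged undefined) for a constant distance matrix.
    """
    arr = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("cophenetic coefficient needs >= 3 samples")
    dist = squareform(1.0 - arr, checks=False)
    if np.ptp(dist) == 0:
        return np.nan
    Z = hierarchy.linkage(dist, method="average")
    rho, _ = hierarchy.cophenet(Z, dist)
    return float(rho)


# ---------------------------------------------------------------------------
# labeling and scores
# ---------------------------------------------------------------------------

LABEL_HIGH = "RMPA_high"
LABEL_LOW = "RMPA_low"


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # sample -> RMPA_high / RMPA_low
    coefficients: pd.DataFrame | None  # H matrix (k x samples), when from NMF
    consensus_support: pd.Series | None  # mean within-cluster consensus
    centroids: pd.DataFrame  # module x label mean standardized expression
    scores: pd.Series | None = None  # continuous RMPA score
    discordant: bool = False  # 2-1 centroid vote

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels})
        if self.consensus_support is not None:
            df["consensus_support"] = self.consensus_support
        if self.scores is not None:
            df["rmpa_score"] = self.scores
        return df.sort_index()


def _module_zscores(expr: ExpressionMatrix, modules: list[CoexpressionModule]) -> dict[str, pd.DataFrame]:
    """Per-module z-scored member expression, keyed by module name."""
    out = {}
    for m in modules:
        rows = _module_rows(expr, m)
        if not rows:
            raise ValueError(f"module {m.name} has no members in the matrix")
        sub = expr.values.loc[rows]
        sub = sub.loc[sub.to_numpy().std(axis=1) > 0]
        if sub.empty:
            raise ValueError(f"module {m.name} has no usable (non-constant) members")
        out[m.name] = _zscore_rows(sub)
    return out


def _module_key(name: str) -> str:
    """Canonical module role from its name: 'spry', 'nf1' or 'pten'."""
    low = name.lower()
    for key in ("spry", "nf1", "pten"):
        if key in low:
            return key
    raise ValueError(f"cannot infer module role from name {name!r}")


def label_subtypes(
    cluster_labels: pd.Series,
    expr: ExpressionMatrix,
    modules: list[CoexpressionModule],
    consensus: pd.DataFrame | None = None,
    coefficients: pd.DataFrame | None = None,
) -> SubtypeAssignment:
    """Orient two clusters into RMPA-high / RMPA-low by module centroids.

    A cluster wins RMPA-high by majority over three votes: higher SPRY-M
    centroid, lower NF1-M centroid, lower PTEN-M centroid.  A 2-1 vote is
    accepted with a logged discordant-pattern flag.
    """
    clusters = pd.unique(cluster_labels)
    if len(clusters) != 2:
        raise ValueError(f"exactly 2 clusters required, got {len(clusters)}")
    zmods = _module_zscores(expr, modules)
    centroids = pd.DataFrame(
        {
            m.name: {
                c: float(zmods[m.name][cluster_labels.index[cluster_labels == c]].mean().mean())
                for c in clusters
            }
            for m in modules
        }
    ).T  # rows = modules, columns = cluster ids
    roles = {_module_key(m.name): m.name for m in modules}
    a, b = clusters
    votes_a = (
        int(centroids.loc[roles["spry"], a] > centroids.loc[roles["spry"], b])
        + int(centroids.loc[roles["nf1"], a] < centroids.loc[roles["nf1"], b])
        + int(centroids.loc[roles["pten"], a] < centroids.loc[roles["pten"], b])
    )
    high_cluster = a if votes_a >= 2 else b
    discordant = votes_a in (1, 2)
    if discordant:
        logger.warning("discordant module pattern: centroid vote %d-%d", votes_a, 3 - votes_a)
    labels = cluster_labels.map(
        lambda c: LABEL_HIGH if c == high_cluster else LABEL_LOW
    )
    support = None
    if consensus is not None:
        support = pd.Series(
            {
                s: float(
                    consensus.loc[s, cluster_labels.index[cluster_labels == cluster_labels[s]]].mean()
                )
                for s in cluster_labels.index
            }
        )
    centroids.columns = [
        LABEL_HIGH if c == high_cluster else LABEL_LOW for c in centroids.columns
    ]
    return SubtypeAssignment(
        labels=labels,
        coefficients=coefficients,
        consensus_support=support,
        centroids=centroids,
        scores=rmpa_score(expr, modules),
        discordant=discordant,
    )


def rmpa_score(expr: ExpressionMatrix, modules: list[CoexpressionModule]) -> pd.Series:
    """Continuous RMPA signature score per sample.

    score = mean z(SPRY-M) - (mean z(NF1-M) + mean z(PTEN-M)) / 2: the two
    repression modules are half-weighted so they jointly balance the single
    induction module.  Higher scores are more RMPA-high-like.
    """
    zmods = _module_zscores(expr, modules)
    roles = {_module_key(name): name for name in zmods}
    means = {key: zmods[name].mean(axis=0) for key, name in roles.items()}
    return means["spry"] - 0.5 * (means["nf1"] + means["pten"])


def classify(
    expr: ExpressionMatrix,
    modules: list[CoexpressionModule],
    k: int = 2,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[SubtypeAssignment, ConsensusResult]:
    """End-to-end: signature -> consensus NMF at k=2 -> oriented labels."""
    sig = build_signature_matrix(expr, modules)
    res = consensus_cluster(sig, k_values=(k,), n_runs=n_runs, base_seed=seed,
                            max_iter=max_iter, tol=tol)[k]
    assignment = label_subtypes(
        res.labels, expr, modules, consensus=res.consensus
    )
    return assignment, res


def hierarchical_split(
    expr: ExpressionMatrix,
    modules: list[CoexpressionModule],
    sample_ids: list[str] | None = None,
) -> pd.Series:
    """Split a sample subset into signature-high / signature-low groups.

    Average-linkage hierarchical clustering on Euclidean distances of the
    standardized module-signature submatrix, cut into two; the group with
    the higher mean RMPA score is labeled "high".  Identical samples give a
    degenerate (arbitrary but deterministic) split, flagged in the log.
    """
    samples = sample_ids if sample_ids is not None else expr.sample_ids
    if len(samples) < 4:
        raise ValueError("hierarchical split needs >= 4 samples")
    sub = ExpressionMatrix(expr.values[samples])
    zmods = _module_zscores(expr, modules)  # standardize over the full cohort
    mat = pd.concat([z[samples] for z in zmods.values()]).to_numpy().T
    from scipy.spatial.distance import pdist

    dist = pdist(mat, metric="euclidean")
    if np.ptp(dist) == 0:
        logger.warning("hierarchical_split: identical samples, degenerate split")
    Z = hierarchy.linkage(dist, method="average")
    groups = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    scores = rmpa_score(expr, modules)[samples]
    mean_by_group = {g: scores[np.asarray(groups) == g].mean() for g in np.unique(groups)}
    high_group = max(mean_by_group, key=mean_by_group.get)
    return pd.Series(
        ["high" if g == high_group else "low" for g in groups], index=samples
    )
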