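"""Copy-number calls, arm summaries, gene-dosage correlation, and
co-occurrence / mutual-exclusivity testing.

Copy-number states come from fixed log2-ratio thresholds (gain >= 0.25,
loss <= -0.2, high-level gain >= 0.7, homozygous loss <= -1.1); gain/loss
are single-copy changes, high-level gain two or more copies.  Arm-level
events use a fraction-of-genes rule.  Pairwise alteration dependence is
tested with the odds ratio and the two-sided Fisher exact test ("tables no
more probable than observed" convention), with Benjamini-Hochberg FDR
across pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import AlterationTable, CopyNumberMatrix

logger = logging.getLogger("rmpa")

COPY_CALLS = ("homozygous_loss", "loss", "neutral", "gain", "high_gain")

# log2-ratio call thresholds, all inclusive
THRESHOLD_GAIN = 0.25
THRESHOLD_LOSS = -0.2
THRESHOLD_HIGH_GAIN = 0.7
THRESHOLD_HOMOZYGOUS_LOSS = -1.1


def call_copy_number(log2_ratio: float) -> str:
    """Classify a log2 copy-number ratio into one of five states."""
    r = float(log2_ratio)
    if not np.isfinite(r):
        raise ValueError(f"log2 ratio must be finite, got {r}")
    if r >= THRESHOLD_HIGH_GAIN:
        return "high_gain"
    if r >= THRESHOLD_GAIN:
        return "gain"
    if r <= THRESHOLD_HOMOZYGOUS_LOSS:
        return "homozygous_loss"
    if r <= THRESHOLD_LOSS:
        return "loss"
    return "neutral"


def call_matrix(cnv: CopyNumberMatrix) -> pd.DataFrame:
    """Vectorized copy-number calls for a whole gene x sample matrix."""
    r = cnv.values.to_numpy()
    if not np.isfinite(r).all():
        raise ValueError("copy-number matrix contains non-finite values")
    out = np.full(r.shape, "neutral", dtype=object)
    out[r <= THRESHOLD_LOSS] = "loss"
    out[r <= THRESHOLD_HOMOZYGOUS_LOSS] = "homozygous_loss"
    out[r >= THRESHOLD_GAIN] = "gain"
    out[r >= THRESHOLD_HIGH_GAIN] = "high_gain"
    return pd.DataFrame(out, index=cnv.values.index, columns=cnv.values.columns)


def arm_summary(
    cnv: CopyNumberMatrix,
    labels: pd.Series,
    arm_frac: float = 0.7,
) -> pd.DataFrame:
    """Per (arm, subtype) fraction of samples with arm-level gain or loss.

    A sample carries an arm-level gain (loss) when at least ``arm_frac`` of
    the arm's genes are called gain-or-higher (loss-or-lower).
    """
    if cnv.arm_map is None:
        raise ValueError("copy-number matrix has no arm annotation")
    labels = labels.reindex(cnv.sample_ids).dropna()
    for subtype, n in labels.value_counts().items():
        if n == 0:
            raise ValueError(f"subtype {subtype!r} has no samples")
    if labels.empty:
        raise ValueError("no samples with subtype labels")
    calls = call_matrix(cnv)
    rows = []
    for arm in pd.unique(cnv.arm_map):
        genes = cnv.arm_map[cnv.arm_map == arm].index.intersection(calls.index)
        if len(genes) == 0:
            logger.warning("arm %s has no genes in the matrix; skipped", arm)
            continue
        sub = calls.loc[genes, labels.index]
        gain_frac = sub.isin(["gain", "high_gain"]).mean(axis=0)
        loss_frac = sub.isin(["loss", "homozygous_loss"]).mean(axis=0)
        arm_gain = gain_frac >= arm_frac
        arm_loss = loss_frac >= arm_frac
        for subtype in pd.unique(labels):
            mask = labels == subtype
            rows.append(
                {
                    "arm": arm,
                    "subtype": subtype,
                    "gain_fraction": float(arm_gain[mask.index[mask]].mean()),
                    "loss_fraction": float(arm_loss[mask.index[mask]].mean()),
                    "n_samples": int(mask.sum()),
                    "n_genes": len(genes),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DosageCorrelation:
    rho: float
    p_value: float
    n: int
    undefined: bool = False


def dosage_correlation(
    expression,
    copies,
    rng: np.random.Generator | None = None,
) -> DosageCorrelation:
    """Spearman correlation between a gene's expression and its dosage.

    Mid-ranks handle ties.  The p-value uses the t approximation for n > 10
    and an exact/sampled permutation null for n <= 10 (full enumeration up
    to n = 7, 10,000 sampled pairings beyond).
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(copies, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DosageCorrelation(np.nan, np.nan, x.size, undefined=True)
    rho, p_approx = stats.spearmanr(x, y)
    n = x.size
    if n > 10:
        return DosageCorrelation(float(rho), float(p_approx), n)

    def statistic(perm_x):
        return stats.spearmanr(perm_x, y).statistic

    res = stats.permutation_test(
        (x,),
        statistic,
        permutation_type="pairings",
        n_resamples=np.inf if n <= 7 else 10_000,
        alternative="two-sided",
        rng=rng if rng is not None else np.random.default_rng(0),
    )
    return DosageCorrelation(float(rho), float(res.pvalue), n)


@dataclass
class AssociationResult:
    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float  # Haldane-corrected when any cell is 0
    raw_odds_ratio: float  # may be inf or 0
    p_value: float
    verdict: str  # co-occurring | exclusive-tendency | independent


def _fisher_and_or(both: int, a_only: int, b_only: int, neither: int, alpha: float):
    table = np.array([[both, a_only], [b_only, neither]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if min(both, a_only, b_only, neither) == 0:
        bc, ac, bo, ne = (v + 0.5 for v in (both, a_only, b_only, neither))
        or_corrected = (bc * ne) / (ac * bo)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.float64(both) * neither / (np.float64(a_only) * b_only)
        raw_or = float(raw) if np.isfinite(raw) else float("inf") if both * neither > 0 else float(raw)
    else:
        or_corrected = raw_or = (both * neither) / (a_only * b_only)
    if p <= alpha and or_corrected > 1:
        verdict = "co-occurring"
    elif p <= alpha and or_corrected < 1:
        verdict = "exclusive-tendency"
    else:
        verdict = "independent"
    return float(or_corrected), float(raw_or), p, verdict


def fisher_from_counts(
    both: int, a_only: int, b_only: int, neither: int, alpha: float = 0.05,
    gene_a: str = "A", gene_b: str = "B",
) -> AssociationResult:
    """Association test directly from 2x2 counts (both, A-only, B-only, neither)."""
    if min(both, a_only, b_only, neither) < 0:
        raise ValueError("counts must be nonnegative")
    or_c, raw_or, p, verdict = _fisher_and_or(both, a_only, b_only, neither, alpha)
    return AssociationResult(
        gene_a, gene_b, both, a_only, b_only, neither, or_c, raw_or, p, verdict
    )


def fisher_cooccurrence(
    alterations: AlterationTable,
    gene_a: str,
    gene_b: str,
    alpha: float = 0.05,
    layer: str = "any",
) -> AssociationResult:
    """Odds ratio + two-sided Fisher exact test between two genes' alterations.

    ``layer`` selects an alteration class or "any" for the OR of all classes.
    The odds ratio gets a +0.5 Haldane correction to every cell when any
    cell is zero (the raw infinite/zero OR is reported alongside).
    """
    mat = alterations.any_alteration if layer == "any" else alterations.layers[layer]
    for g in (gene_a, gene_b):
        if g not in mat.index:
            raise ValueError(f"gene {g!r} not in alteration table")
    a = mat.loc[gene_a].to_numpy().astype(bool)
    b = mat.loc[gene_b].to_numpy().astype(bool)
    if not (a.any() or b.any()):
        raise ValueError("neither gene altered in any sample")
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    return fisher_from_counts(
        both, a_only, b_only, neither, alpha, gene_a=gene_a, gene_b=gene_b
    )


def pairwise_associations(
    alterations: AlterationTable,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    layer: str = "any",
) -> pd.DataFrame:
    """Association tests over gene pairs with BH-FDR across the pair set."""
    if pairs is None:
        pairs = list(itertools.combinations(alterations.gene_ids, 2))
    results = [fisher_cooccurrence(alterations, a, b, alpha, layer) for a, b in pairs]
    df = pd.DataFrame([vars(r) for r in results])
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
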