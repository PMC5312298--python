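"""Synthetic glioma cohorts with planted ground truth.

The generator reproduces the statistical structure the pipeline assumes,
with every planted feature recorded for testing:

* expression follows a one-factor-per-module model: each sample carries a
  latent subtype (high/low); module factors sit at +delta or -delta by
  subtype (SPRY-M up in the high subtype, NF1-M/PTEN-M down, mirrored in
  the low subtype) plus standard-normal jitter, and member genes load on
  their module's factor with per-gene loadings drawn from a range, plus
  Gaussian residual noise; one seed gene per module carries the maximum
  loading; background genes are pure noise;
* overall survival is exponential with a subtype hazard ratio and uniform
  censoring tuned to a target censoring fraction;
* copy number plants subtype-skewed arm events (chr7 gain, chr10 loss in
  the high subtype) whose genes take integer copies 0..4; designated dosage
  genes shift their expression by dosage_beta per copy deviation from 2;
* binary alterations plant one mutually-exclusive and one co-occurring
  gene pair at target odds ratios, all other genes independent Bernoulli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .data_io import (
    AlterationTable,
    ClinicalTable,
    CopyNumberMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
)
from .module_discovery import CoexpressionModule
from .rmpa_classifier import LABEL_HIGH, LABEL_LOW, SubtypeAssignment

MODULE_NAMES = ("SPRY-M", "NF1-M", "PTEN-M")
#: module factor orientation in the high subtype
_MODULE_SIGN = {"SPRY-M": +1.0, "NF1-M": -1.0, "PTEN-M": -1.0}
_SEED_GENES = {"SPRY-M": "SPRY1", "NF1-M": "NF1", "PTEN-M": "PTEN"}

#: planted alteration pairs (glioma-flavored gene names)
EXCLUSIVE_PAIR = ("EGFR", "NF1alt")
COOCCURRING_PAIR = ("PDGFRA", "KIT")
_INDEPENDENT_ALT_GENES = ("KDR", "MET", "CDKN2A", "TP53")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 200
    prop_high: float = 0.5
    module_sizes: dict = field(
        default_factory=lambda: {"SPRY-M": 30, "NF1-M": 30, "PTEN-M": 30}
    )
    loading_range: tuple[float, float] = (0.5, 1.0)
    effect_delta: float = 1.5
    noise_sd: float = 1.0
    n_background_genes: int = 200
    hazard_ratio: float = 2.5
    censor_frac: float = 0.3
    dosage_beta: float = 0.8
    excl_odds_ratio: float = 0.2
    cooc_odds_ratio: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prop_high < 1:
            raise ValueError("prop_high must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if any(s < 2 for s in self.module_sizes.values()):
            raise ValueError("module sizes must be >= 2")
        if self.prop_high * self.n_samples < 2 or (1 - self.prop_high) * self.n_samples < 2:
            raise ValueError("expected subtype count below 2: infeasible config")


@dataclass
class GroundTruth:
    subtype: pd.Series  # sample -> RMPA_high / RMPA_low
    module_members: dict[str, set[str]]  # module -> gene set (includes seed)
    seed_genes: dict[str, str]
    loadings: pd.Series  # gene -> lambda
    hazard_ratio: float
    excl_odds_ratio: float
    cooc_odds_ratio: float
    dosage_genes: list[str]
    copies: pd.DataFrame  # dosage/arm gene x sample integer copies

    def modules(self) -> list[CoexpressionModule]:
        """Planted modules as CoexpressionModule objects (probe = <gene>_at)."""
        return [
            CoexpressionModule(
                name=name,
                seed_probes=[f"{self.seed_genes[name]}_at"],
                member_probes={f"{g}_at" for g in members},
                member_genes=set(members),
                n_top=len(members),
                seed_genes={self.seed_genes[name]},
            )
            for name, members in self.module_members.items()
        ]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    annotation: ProbeAnnotation
    clinical: ClinicalTable
    copy_number: CopyNumberMatrix
    alterations: AlterationTable
    truth: GroundTruth
    config: CohortConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _uniform_censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound c of U(0, c) censoring giving expected censor fraction
    ``target`` for exponential event times with per-subject ``rates``."""
    from scipy.optimize import brentq

    def frac(c):
        lc = rates * c
        return float(np.mean((1 - np.exp(-lc)) / lc)) - target

    # frac is decreasing in c from 1-target (c->0) to -target (c->inf)
    return brentq(frac, 1e-6, 1e6)


def _pair_cell_probs(p_a: float, p_b: float, odds_ratio: float) -> np.ndarray:
    """2x2 cell probabilities [p11, p10, p01, p00] with given margins and OR
    (Plackett construction)."""
    if abs(odds_ratio - 1.0) < 1e-12:
        p11 = p_a * p_b
    else:
        s = 1 + (p_a + p_b) * (odds_ratio - 1)
        disc = s * s - 4 * odds_ratio * (odds_ratio - 1) * p_a * p_b
        p11 = (s - np.sqrt(disc)) / (2 * (odds_ratio - 1))
    return np.array([p11, p_a - p11, p_b - p11, 1 - p_a - p_b + p11])


#: arm-event genes: (gene, arm, direction); chr7 gain / chr10 loss skewed to
#: the high subtype, matching the amplification-coupled-with-loss pattern
_ARM_GENES = [
    ("EGFR_cn", "7p", "gain"), ("CDK6_cn", "7q", "gain"), ("MET_cn", "7q", "gain"),
    ("BRAF_cn", "7q", "gain"), ("IKZF1_cn", "7p", "gain"), ("EZH2_cn", "7q", "gain"),
    ("PTEN_cn", "10q", "loss"), ("MGMT_cn", "10q", "loss"), ("GATA3_cn", "10p", "loss"),
    ("KLF6_cn", "10p", "loss"), ("FGFR2_cn", "10q", "loss"), ("BMI1_cn", "10p", "loss"),
]
#: P(arm event) per subtype
_ARM_EVENT_P = {"gain": {LABEL_HIGH: 0.8, LABEL_LOW: 0.15},
                "loss": {LABEL_HIGH: 0.75, LABEL_LOW: 0.2}}


def generate(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort; same config + seed is bit-reproducible.

    Independent RNG streams per data layer (subtype, expression, survival,
    copy number, alterations) are spawned from the master seed so layers
    can be regenerated independently.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_subtype, rng_expr, rng_surv, rng_cn, rng_alt = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    # latent subtype
    z = rng_subtype.random(n) < config.prop_high
    subtype = pd.Series(np.where(z, LABEL_HIGH, LABEL_LOW), index=samples)

    # --- expression -------------------------------------------------------
    lo, hi = config.loading_range
    gene_rows, loadings, module_members = [], {}, {}
    expr_blocks = []
    for name in MODULE_NAMES:
        size = config.module_sizes[name]
        seed_gene = _SEED_GENES[name]
        members = [seed_gene] + [f"{name.split('-')[0]}m_g{i:03d}" for i in range(1, size)]
        module_members[name] = set(members)
        lam = np.empty(size)
        lam[0] = hi  # seed gene carries the maximum loading
        lam[1:] = rng_expr.uniform(lo, hi, size - 1)
        for g, l in zip(members, lam):
            loadings[g] = float(l)
        sign = _MODULE_SIGN[name]
        factor = sign * np.where(z, config.effect_delta, -config.effect_delta)
        factor = factor + rng_expr.standard_normal(n)
        block = lam[:, None] * factor[None, :] + rng_expr.normal(
            0.0, config.noise_sd, (size, n)
        )
        gene_rows.extend(members)
        expr_blocks.append(block)
    background = [f"BG_g{i:04d}" for i in range(config.n_background_genes)]
    gene_rows.extend(background)
    expr_blocks.append(rng_expr.normal(0.0, config.noise_sd,
                                       (config.n_background_genes, n)))
    expr_values = np.vstack(expr_blocks) + 8.0  # log2-scale baseline
    expr_df = pd.DataFrame(expr_values, index=gene_rows, columns=samples)

    # --- survival ---------------------------------------------------------
    h0 = np.log(2) / 36.0  # baseline: 36-month median survival in the low group
    rates = h0 * np.where(z, config.hazard_ratio, 1.0)
    event_times = rng_surv.exponential(1.0 / rates)
    if config.censor_frac > 0:
        c_max = _uniform_censor_bound(rates, config.censor_frac)
        censor_times = rng_surv.uniform(0.0, c_max, n)
        observed = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        observed, event = event_times, np.ones(n, dtype=int)
    grade_p = {LABEL_HIGH: [0.1, 0.3, 0.6], LABEL_LOW: [0.4, 0.4, 0.2]}
    grades = [
        rng_surv.choice(["II", "III", "IV"], p=grade_p[s]) for s in subtype
    ]
    morph = {"II": "astrocytoma", "III": "anaplastic astrocytoma", "IV": "glioblastoma"}
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": np.maximum(observed, 1e-3),
                "event": event,
                "grade": grades,
                "age": np.clip(rng_surv.normal(50, 12, n).round(1), 18, 90),
                "morphology": [morph[g] for g in grades],
            },
            index=samples,
        )
    )

    # --- copy number ------------------------------------------------------
    arms = sorted({arm for _, arm, _ in _ARM_GENES})
    arm_state = {}
    for arm in arms:
        direction = next(d for _, a, d in _ARM_GENES if a == arm)
        p = np.array([_ARM_EVENT_P[direction][s] for s in subtype])
        arm_state[arm] = rng_cn.random(n) < p
    copies = {}
    for gene, arm, direction in _ARM_GENES:
        ev = arm_state[arm]
        if direction == "gain":
            c = np.where(ev, np.where(rng_cn.random(n) < 0.25, 4, 3), 2)
        else:
            c = np.where(ev, np.where(rng_cn.random(n) < 0.1, 0, 1), 2)
        copies[gene] = c
    copies_df = pd.DataFrame(copies, index=samples).T
    log2_ratio = np.log2(np.maximum(copies_df.to_numpy(), 0.25) / 2.0)
    log2_ratio = log2_ratio + rng_cn.normal(0.0, 0.03, log2_ratio.shape)
    cnv = CopyNumberMatrix(
        pd.DataFrame(log2_ratio, index=copies_df.index, columns=samples),
        arm_map=pd.Series({g: a for g, a, _ in _ARM_GENES}),
    )
    # dosage effect: each arm gene shadows one background expression gene
    # (capped by the number of background genes available)
    dosage_genes = [g for g, _, _ in _ARM_GENES][: len(background)]
    for i, gene in enumerate(dosage_genes):
        target_row = background[i]
        expr_df.loc[target_row] += config.dosage_beta * (copies_df.loc[gene].to_numpy() - 2)

    # --- annotation (one probe per gene, GEO-style probe ids) -------------
    probes = {f"{g}_at": g for g in gene_rows}
    annotation = ProbeAnnotation(pd.Series(probes))
    expr_probe_df = expr_df.copy()
    expr_probe_df.index = [f"{g}_at" for g in expr_df.index]
    expression = ExpressionMatrix(expr_probe_df)

    # --- alterations ------------------------------------------------------
    layers = {
        cls: pd.DataFrame(
            0,
            index=list(EXCLUSIVE_PAIR) + list(COOCCURRING_PAIR) + list(_INDEPENDENT_ALT_GENES),
            columns=samples,
            dtype=int,
        )
        for cls in ("amplification", "deletion", "mutation")
    }

    def plant_pair(pair, odds_ratio, class_a, class_b):
        probs = _pair_cell_probs(0.35, 0.35, odds_ratio)
        cells = rng_alt.choice(4, size=n, p=probs)
        layers[class_a].loc[pair[0]] = np.isin(cells, [0, 1]).astype(int)
        layers[class_b].loc[pair[1]] = np.isin(cells, [0, 2]).astype(int)

    plant_pair(EXCLUSIVE_PAIR, config.excl_odds_ratio, "amplification", "mutation")
    plant_pair(COOCCURRING_PAIR, config.cooc_odds_ratio, "amplification", "amplification")
    for gene in _INDEPENDENT_ALT_GENES:
        layers["mutation"].loc[gene] = (rng_alt.random(n) < 0.2).astype(int)
    alterations = AlterationTable(layers)

    truth = GroundTruth(
        subtype=subtype,
        module_members=module_members,
        seed_genes=dict(_SEED_GENES),
        loadings=pd.Series(loadings),
        hazard_ratio=config.hazard_ratio,
        excl_odds_ratio=config.excl_odds_ratio,
        cooc_odds_ratio=config.cooc_odds_ratio,
        dosage_genes=dosage_genes,
        copies=copies_df,
    )
    return SyntheticCohort(expression, annotation, clinical, cnv, alterations, truth, config)


def dosage_pairs(cohort: SyntheticCohort) -> list[tuple[pd.Series, pd.Series]]:
    """(expression, integer copies) pairs for the planted dosage genes."""
    out = []
    background = [p for p in cohort.expression.row_ids if p.startswith("BG_")]
    for i, gene in enumerate(cohort.truth.dosage_genes):
        expr_row = cohort.expression.values.loc[background[i]]
        out.append((expr_row, cohort.truth.copies.loc[gene]))
    return out


# ---------------------------------------------------------------------------
# truth metrics
# ---------------------------------------------------------------------------

def planted_module_overlap(cohort: SyntheticCohort, discovered: CoexpressionModule) -> float:
    """|discovered genes ∩ planted genes| / |planted genes| for the module
    whose name matches the discovered module's."""
    if not discovered.member_genes and not discovered.member_probes:
        raise ValueError("discovered module is empty")
    matches = [n for n in cohort.truth.module_members if
               n.split("-")[0].lower() in discovered.name.lower()]
    if not matches:
        raise ValueError(f"unknown module name {discovered.name!r}")
    truth_genes = cohort.truth.module_members[matches[0]]
    recovered = discovered.member_genes | discovered.seed_genes
    return len(recovered & truth_genes) / len(truth_genes)


def truth_agreement(
    assignments: SubtypeAssignment | pd.Series, truth: GroundTruth
) -> tuple[float, float]:
    """(label agreement maximized over permutation, adjusted Rand index)."""
    labels = assignments.labels if isinstance(assignments, SubtypeAssignment) else assignments
    if set(labels.index) != set(truth.subtype.index):
        raise ValueError("assignment and truth cover different samples")
    pred = labels.reindex(truth.subtype.index)
    match = float((pred == truth.subtype).mean())
    agreement = max(match, 1.0 - match)
    codes_pred = pd.Categorical(pred).codes
    codes_true = pd.Categorical(truth.subtype).codes
    ari = float(adjusted_rand_score(codes_true, codes_pred))
    return agreement, ari


# ---------------------------------------------------------------------------
# writing a cohort to disk
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write every cohort table in the pipeline's file formats plus a truth JSON."""
    from . import data_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
        "clinical": out / "clinical.csv",
        "copy_number": out / "copy_number.tsv",
        "arm_map": out / "arm_map.tsv",
        "alterations": out / "alterations.csv",
        "truth": out / "truth.json",
    }
    data_io.write_expression_matrix(cohort.expression, paths["expression"])
    data_io.write_probe_annotation(cohort.annotation, paths["annotation"])
    data_io.write_clinical_table(cohort.clinical, paths["clinical"])
    data_io.write_copy_number_matrix(
        cohort.copy_number, paths["copy_number"], arm_map_path=paths["arm_map"]
    )
    data_io.write_alteration_table(cohort.alterations, paths["alterations"])
    truth = cohort.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "subtype": truth.subtype.to_dict(),
                "module_members": {k: sorted(v) for k, v in truth.module_members.items()},
                "seed_genes": truth.seed_genes,
                "hazard_ratio": truth.hazard_ratio,
                "excl_odds_ratio": truth.excl_odds_ratio,
                "cooc_odds_ratio": truth.cooc_odds_ratio,
                "dosage_genes": truth.dosage_genes,
            },
            indent=2,
        )
    )
    return paths
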