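"""Seed-gene co-expression module discovery.

A module (SPRY-M, NF1-M, PTEN-M style) is the set of probes most correlated
with one or more seed probes: rank every usable probe by Pearson
correlation to the seed across all samples, keep the top N, and for
multi-seed modules intersect the per-seed top-N sets.  Member genes come
from the probe annotation; unannotated probes stay members as probes only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger("rmpa")


@dataclass
class CorrelationRanking:
    """Probes ordered by Pearson correlation to a seed probe (descending)."""

    seed_probe: str
    entries: pd.Series  # index = probe_id, values = r, sorted descending

    def top(self, n: int) -> list[str]:
        return top_n(self, n)


@dataclass
class CoexpressionModule:
    name: str
    seed_probes: list[str]
    member_probes: set[str]
    member_genes: set[str]
    n_top: int
    seed_genes: set[str] = field(default_factory=set)


def pearson_profile(
    expr: ExpressionMatrix,
    seed_probe: str,
    use_abs: bool = False,
    samples: list[str] | None = None,
) -> CorrelationRanking:
    """Correlation of every usable probe against the seed, seed excluded.

    ``use_abs`` ranks by \\|r\\| instead of signed r ("co-expressed" implies
    signed, the default).  ``samples`` restricts the correlation to a sample
    subset (e.g. tumors only).
    """
    values = expr.values if samples is None else expr.values[samples]
    if seed_probe not in values.index:
        raise ValueError(f"seed probe {seed_probe!r} not in expression matrix")
    arr = values.to_numpy(dtype=float)
    seed = values.loc[seed_probe].to_numpy(dtype=float)
    if seed.std() == 0:
        raise ValueError(f"seed probe {seed_probe!r} has zero variance")

    # one-pass centered correlation against the seed for every row
    usable = arr.std(axis=1) > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("pearson_profile(%s): excluded %d zero-variance probe(s)",
                    seed_probe, n_dropped)
    centered = arr - arr.mean(axis=1, keepdims=True)
    seed_c = seed - seed.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ seed_c) / (
            np.sqrt((centered**2).sum(axis=1)) * np.sqrt((seed_c**2).sum())
        )
    keep = usable & (values.index != seed_probe)
    series = pd.Series(r[keep], index=values.index[keep])
    key = series.abs() if use_abs else series
    # descending r, lexicographic probe id on ties (deterministic)
    order = sorted(series.index, key=lambda p: (-key[p], p))
    return CorrelationRanking(seed_probe, series.loc[order])


def top_n(ranking: CorrelationRanking, n: int) -> list[str]:
    """First n probes by r; ties at the cut already broken lexicographically."""
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    entries = ranking.entries
    if n > len(entries):
        warnings.warn(
            f"requested top {n} but only {len(entries)} usable probes; returning all"
        )
        return list(entries.index)
    return list(entries.index[:n])


def intersect_top_sets(rankings: list[CorrelationRanking], n: int) -> set[str]:
    """Probes common to every ranking's top-N."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings to intersect")
    sets = [set(top_n(r, n)) for r in rankings]
    common = set.intersection(*sets)
    if not common:
        warnings.warn("top-N sets have empty intersection")
    return common


def assemble_module(
    expr: ExpressionMatrix,
    annotation: ProbeAnnotation,
    seeds: list[str],
    n_top: int = 100,
    combine: str = "single",
    name: str = "custom",
    use_abs: bool = False,
    include_seeds: bool = False,
    samples: list[str] | None = None,
) -> CoexpressionModule:
    """Build a co-expression module around seed probe(s).

    ``combine="single"`` takes one seed's top-N; ``combine="intersect"``
    intersects the top-N sets of >=2 seeds.  Seed probes are excluded from
    their own rankings (self-correlation is trivially 1); ``include_seeds``
    adds them back to the membership.
    """
    if combine == "single" and len(seeds) != 1:
        raise ValueError("combine='single' requires exactly one seed")
    if combine == "intersect" and len(seeds) < 2:
        raise ValueError("combine='intersect' requires >= 2 seeds")
    rankings = [pearson_profile(expr, s, use_abs=use_abs, samples=samples) for s in seeds]
    if combine == "single":
        members = set(top_n(rankings[0], n_top))
    else:
        members = intersect_top_sets(rankings, n_top)
    members -= set(seeds)
    if include_seeds:
        members |= set(seeds)
    genes = annotation.genes_of(members)
    n_unannotated = len(members) - sum(
        annotation.gene_of(p) != ProbeAnnotation.UNANNOTATED for p in members
    )
    if n_unannotated:
        logger.info("module %s: %d unannotated probe(s) excluded from gene list",
                    name, n_unannotated)
    return CoexpressionModule(
        name=name,
        seed_probes=list(seeds),
        member_probes=members,
        member_genes=genes,
        n_top=n_top,
        seed_genes=annotation.genes_of(seeds),
    )


def modules_membership_table(
    modules: list[CoexpressionModule], annotation: ProbeAnnotation
) -> pd.DataFrame:
    """Membership table (module, probe, gene) for writing to TSV."""
    rows = [
        {"module": m.name, "probe": p, "gene": annotation.gene_of(p)}
        for m in modules
        for p in sorted(m.member_probes)
    ]
    return pd.DataFrame(rows, columns=["module", "probe", "gene"])
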