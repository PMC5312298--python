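# rmpa — glioma subtyping by RTK-pathway module expression

Diffuse gliomas differ widely in how strongly the RAS–RAF–MEK–MAPK and
PI3K–AKT cascades downstream of receptor tyrosine kinases (RTKs) are
engaged, and that difference tracks survival and genomic makeup more
closely than morphology does.  This package implements an analysis
pipeline that quantifies this axis from bulk expression data and is aimed
at computational biologists working with tumor expression cohorts:

1. **Module discovery** — build gene co-expression modules around
   pathway-sentinel seed genes: the sprouty genes (*SPRY1/2/4*,
   ligand-induced RTK-signaling inhibitors, **SPRY-M**), *NF1* (RAS-GAP,
   **NF1-M**) and *PTEN* (PI3K antagonist, **PTEN-M**).  A module is the
   top-*N* probe set by Pearson correlation to its seed (intersected
   across seeds for SPRY-M).
2. **Subtype classification** — standardize the module signature, make it
   nonnegative by signed folding (each z-scored gene row splits into
   max(z,0) and max(−z,0) rows), and cluster samples by consensus
   non-negative matrix factorization (KL-divergence multiplicative
   updates, many random restarts).  Cluster stability is measured by the
   cophenetic coefficient of the consensus matrix; at k = 2 the clusters
   are the **RMPA<sup>high</sup>** subtype (SPRY-M up, NF1-M/PTEN-M down —
   high combined MAPK/AKT activity) and the mirrored
   **RMPA<sup>low</sup>** subtype.
3. **Downstream associations** — Kaplan–Meier / log-rank survival
   comparison (overall and per WHO grade), threshold-based copy-number
   calls (gain ≥ 0.25, loss ≤ −0.2, high-level gain ≥ 0.7, homozygous
   loss ≤ −1.1 on log2 ratios) with arm-level frequency summaries,
   gene-dosage Spearman correlation, odds-ratio/Fisher exact tests for
   alteration co-occurrence and mutual exclusivity, and immunoreactive
   score (IRS = percentage bin 1–4 × intensity grade 0–3) comparison.

Because the consortium cohorts behind such analyses cannot be bundled, the
package ships a first-class synthetic-cohort generator
(`rmpa.synthetic_cohort`) that plants every piece of structure the
pipeline assumes — modules, subtypes, survival hazard, dosage effects,
alteration dependence — with full ground truth, so every stage is testable
end to end.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
synthetic cohort (outputs under `results/`):

```bash
python analysis/01_simulate.py --seed 1          # cohort + ground truth
python analysis/02_discover_modules.py           # seed-gene modules
python analysis/03_classify.py --seed 1          # NMF consensus subtypes
python analysis/04_survival.py                   # KM + log-rank
python analysis/05_genomic_alterations.py        # SCNA calls + Fisher tests
python analysis/06_ihc.py --seed 1               # IRS comparison
```

With seed 1 (200 samples) the run prints, among other lines:

```
SPRY-M: 30 probes, 30/30 planted genes recovered
cophenetic: k=2 1.0000, k=3 0.9947, k=4 0.9795
agreement with planted subtypes: 0.990
overall log-rank: chi2=18.907, p=1.37e-05
  RMPA_low: n=101, median survival 37.0 months
  RMPA_high: n=99, median survival 17.2 months
 7p RMPA_high  gain_fraction 0.838
  EGFR NF1alt  OR 0.1055  p 0.0000  exclusive-tendency
   KIT PDGFRA  OR 3.6601  p 0.0001  co-occurring
```

i.e. the discovered modules recover the planted membership, consensus NMF
is most stable at k = 2 and reproduces the planted subtypes at 99%
agreement, the RMPA-high subtype shows the planted survival disadvantage
(median 17 vs 37 months), ~80% of RMPA-high tumors carry the planted
chromosome-7p gain, and the planted exclusive (OR 0.2) and co-occurring
(OR 5) alteration pairs are both detected with the correct verdicts.

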