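# pmmetab

Time-since-death dependence of endogenous compounds in postmortem femoral
blood: a tested analysis pipeline for paired two-time-point peak-area
tables from targeted LC-HRMS.

## The problem

Postmortem metabolomics works with blood drawn hours to weeks after death.
Concentrations of amino acids, acylcarnitines, phospholipids and other
endogenous compounds drift with the postmortem interval (PMI), so any
case/control comparison on autopsy material is confounded by *when* the
blood was collected. The design addressed here pairs two femoral-blood
samples per case — one at mortuary admission (t1), one at autopsy (t2),
both measured in the same instrument batch — so that the collection
interval Δt = t2 − t1 is the only variable within a case.

The pipeline implements, for a 38-compound panel:

- a panel registry with formula parsing and monoisotopic-mass computation;
- a synthetic cohort generator emulating the study structure (427 cases,
  17 batches, 5 pooled-QC injections per batch, 3 isotope-labelled
  internal standards, four temporal drift patterns) with full ground truth;
- quality gates: Grubbs outlier screening on batch-normalized IS areas
  (excluding a sample only when flagged on *all three* standards), RSD
  criteria, pool drift checks;
- normalization: pool-based batch correction, IS division, probabilistic
  quotient normalization (PQN);
- paired inference: per-case percent change 100·(A_t2 − A_t1)/A_t1 on raw
  areas, Δt bins (0–12 h … >144 h), Wilcoxon signed-rank with Holm
  adjustment across the analyte family, order-statistic median CIs;
- unpaired inference: all samples binned by their own time since death
  into ten groups, Kruskal–Wallis + Dunn's post-hoc + Holm, percent change
  of group medians vs the earliest group;
- interpretation: four-pattern temporal classification (steady increase /
  lag then increase / decrease / stable, 30% band), Spearman correlations
  with logP / molecular weight / retention time, paired-vs-unpaired
  concordance, and a normalization-mode comparison quantifying how PQN
  attenuates temporal effects when most of a small panel drifts.

The statistics engine (Wilcoxon, Mann–Whitney, Kruskal–Wallis, Dunn, Holm,
Spearman, median CIs) is self-contained, with exact small-sample branches
verified against full enumeration oracles. See `docs/methods.md` for the
model and every convention.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/04_paired_changes.py
```

prints, for the default seeded cohort:

```
cohort: 427 cases, 939 samples, 38 analytes
median t1 = 9.2 h (range 1.3-225 h)
median delta-t = 74.8 h (range 8.5-407 h)
...
26/38 analytes change significantly between t2 and t1 (Holm-adjusted p < 0.05)

largest median increases:
             analyte  median_pct  p_adj code
         Cholic acid     201.888    0.0  ***
             Taurine     139.644    0.0  ***
      Carnitine (C0)     100.370    0.0  ***
```

i.e. on a cohort whose generating kinetics follow the published pattern
taxonomy, bile acids, taurine and short-chain carnitines show the largest
median increases from admission to autopsy, medium-chain acylcarnitines
decrease, and the Holm-adjusted Wilcoxon tests flag the drifting analytes.
`analysis/05_unpaired_time_groups.py` and `analysis/06_interpretation.py`
continue the chain: the per-analyte paired change and the highest unpaired
change against the 0–6 h group agree with Spearman ρ² ≈ 0.92, logP /
molecular weight show no correlation with change magnitude, and the PQN
attenuation ratio ≈ 0.63 shows quotient normalization absorbing real
temporal drift on a majority-drifting panel.

The same stages are available as a library (`pmmetab.run_pipeline`) and as
a CLI (`pmmetab simulate|validate|qc|normalize|paired|unpaired|interpret|run`)
over long-format CSV tables; real study tables in the documented schema
drop in unchanged.

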