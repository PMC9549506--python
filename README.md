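# circstab

Stability analysis of circular versus linear RNA expression under blood
sample-processing delay.

## The problem

Blood RNA biomarkers are fragile: the interval between blood draw and
cell isolation ("processing delay") reshapes the measured transcriptome.
Circular RNAs (circRNAs) — covalently closed transcripts formed by
back-splicing, with no free ends for exonucleases to attack — are
expected to ride out such delays far better than linear mRNAs and
lncRNAs, whose median half-lives are at least 2.5× shorter. `circstab`
implements the transcript-level time-course analysis that quantifies
this: peripheral blood mononuclear cell (PBMC) samples from several
donors, incubated at 4 °C for 0/2/6/12/24/48 h before isolation, profiled
by RNA-seq, and compared per time point against the 0 h baseline.

It is aimed at transcriptomics analysts who have transcript-level count
and TPM matrices (circRNA quantification done upstream at the back-splice
junction level) and want a tested, reproducible implementation of the
complete downstream analysis — plus a synthetic generator that emulates
the study design with full ground truth for calibration and power work.

## What it computes

* **Repertoire construction** — a transcript is kept when TPM ≥ 1 in all
  but at most four samples (strictly: removed iff TPM < 1 in *more than
  four* samples); circRNAs additionally require a protein-coding or
  lncRNA host-gene biotype. Composition statistics per RNA class
  (counts, fractions, TPM shares, circRNA exon/length histograms) and an
  mtRNA-content one-way ANOVA across time points as viability QC.
* **Differential expression** — per-time-point negative-binomial GLM
  likelihood-ratio tests (0 h vs t, donor as fixed covariate):
  median-of-ratios size factors, Cox–Reid profile-likelihood dispersions
  moderated toward a mean–dispersion trend, χ²(1) LRT p-values,
  Benjamini–Hochberg adjustment, MAP-shrunken log₂ fold changes under a
  zero-centred normal prior. Call rule: |log₂FC| > 0.5 and adjusted
  p < .05 (both strict).
* **Dynamic gain/loss** — "expressed" at a time point means TPM > 1 in
  ≥ 2 replicate samples; *newborn* transcripts are expressed at t but not
  at 0 h, *degraded* the reverse.
* **circRNA dysregulation origin** — a dysregulated circRNA whose host
  gene (linear transcripts, summed per gene) moves in the same direction
  is *transcription-derived*; one whose host shows no significant change
  is *splice-derived*; circ–host log₂FC Pearson/Spearman correlation.
* **Differential alternative splicing** — percent spliced in
  Ψ = (I/l_I) / (I/l_I + S/l_S) from inclusion/skipping junction counts
  with effective lengths (rMATS convention), donor-paired t-tests of
  ΔΨ = Ψ(t) − Ψ(0), significance rule p < .05 and |ΔΨ| ≥ .05, and
  per-class rates normalised by the number of identified AS events.
* **Synthetic time course** — exponential decay / induction trajectories
  with log-normal half-lives (circRNA median 2.5× linear), per-donor
  multiplicative effects, NB(μ, α) counts with Var = μ + αμ², and planted
  Ψ shifts over four AS event types (SE, A5SS, A3SS, RI) — all with
  complete ground truth.

## Worked example

```python
from circstab import SimulationConfig, simulate_expression, DifferentialExpressionModel

cfg = SimulationConfig(seed=1)          # 3 donors x 6 time points
study, truth = simulate_expression(cfg)
print(study)
results = DifferentialExpressionModel(study).fit()
print(results.summary().to_string(index=False))
```

```
<ExpressionStudy 1000 transcripts x 18 samples, times=[0.0, 2.0, 6.0, 12.0, 24.0, 48.0]>
rna_class  contrast_time_h  n_dysregulated  class_total  proportion
  circRNA              2.0               8          119    0.067227
   lncRNA              2.0               3           65    0.046154
     mRNA              2.0              45          816    0.055147
  circRNA              6.0              12          119    0.100840
   lncRNA              6.0               3           65    0.046154
     mRNA              6.0              79          816    0.096814
  circRNA             12.0              13          119    0.109244
   lncRNA             12.0               5           65    0.076923
     mRNA             12.0             126          816    0.154412
  circRNA             24.0              17          119    0.142857
   lncRNA             24.0              10           65    0.153846
     mRNA             24.0             168          816    0.205882
  circRNA             48.0              27          119    0.226891
   lncRNA             48.0              13           65    0.200000
     mRNA             48.0             226          816    0.276961
```

Each row is one RNA class at one contrast (that time point vs 0 h):
`n_dysregulated` counts transcripts passing |log₂FC| > 0.5 with adjusted
p < .05, and `proportion` divides by the class size. The dysregulated
proportion grows with incubation time for every class, and from 12 h on
the circRNA proportion stays below the mRNA proportion — the greater
stability of the circular transcripts under processing delay.

The same analysis runs from the shell:

```sh
circstab run --seed 1 --outdir out/        # simulate + full pipeline
circstab simulate --seed 1 --outdir sim/   # synthetic study + ground truth
```

`out/` then holds `de_results.tsv`, `dynamics_proportions.tsv`,
`origin_calls.tsv`, `delta_psi.tsv`, `as_rates.tsv` and a machine-readable
`run_summary.json`.

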