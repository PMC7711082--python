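# fusionsig

Derive, score and evaluate **TMPRSS2-ERG fusion gene signatures** in
prostate-cancer expression cohorts.

The TMPRSS2-ERG fusion joins the androgen-responsive TMPRSS2 promoter to
the ERG transcription factor and occurs in more than half of prostate
cancers, driving a broad downstream transcriptional program. A weighted
gene signature that captures this program can (i) classify tumors by
fusion status from expression alone, (ii) flag fusion-negative tumors
with fusion-like pathway activity (e.g. ERG fused to other partners such
as SLC45A3), and (iii) stratify patients by prognosis. `fusionsig` is a
library for building and validating such signatures, aimed at
computational biologists working with bulk expression cohorts that carry
fusion annotations and clinical follow-up.

## The method

**Derivation.** For every gene *g*, fit a logistic regression

&nbsp;&nbsp;&nbsp;&nbsp;logit P(fusion⁺) = β₀ + β₁·x_g + β₂·age + β₃·Gleason

and take the two-sided Wald p-value of β₁. The *K* most significant
genes (default *K* = 700) form the signature, with weights

&nbsp;&nbsp;&nbsp;&nbsp;w_g = sign(β₁) · (−log₁₀ p_g) / max(−log₁₀ p)

so all weights lie in [−1, 1], the strongest gene anchors |w| = 1, and
the sign marks up-/downregulation in fusion-positive tumors.

**Scoring.** Each sample is scored with a rank-based single-sample
statistic in the BASE family. Genes are ranked by descending expression;
for a magnitude vector *v* (|w| on set genes, 0 elsewhere) the running
foreground share F(k) = Σ_{i≤k} v_i / Σ v_i is compared with the
background share B(k) = Σ_{i≤k} (1−v_i) / Σ (1−v_i), and the pre-score
is F−B at the cut maximizing |F−B|. Pre-scores are normalized by the
mean |pre-score| under seeded permutations of the gene labels, and the
sample score is (normalized up-set score) − (normalized down-set score).
Scores are exactly invariant to monotone transforms of expression and
exactly antisymmetric under weight negation.

**Evaluation.** Wilcoxon rank-sum contrasts of scores between fusion
groups, ROC/AUC by pair counting, median-split Kaplan-Meier curves with
log-rank tests (overall and within strata such as Gleason 7), and
Spearman correlation of the score with continuous covariates (ERG
expression, immune-infiltration fractions, mutation/CNV burdens supplied
as clinical columns).

**Simulation.** A cohort generator plants up/down signal genes whose
shift follows a latent per-sample pathway activity, draws age/Gleason
covariates, and links an exponential proportional-hazards survival model
to the same latent activity — so every stage can be validated against
known ground truth without external data.

## Worked example

```bash
python examples/02_derive_signature.py
```

```
signature size: 60 genes (30 up, 30 down)
planted signal genes recovered: 60/60

strongest entries (|weight| near 1 = most significant):
  G0004  weight +1.000  (truth: up)
  G0008  weight +0.944  (truth: up)
  G0060  weight -0.937  (truth: down)
  G0023  weight +0.929  (truth: up)
  G0014  weight +0.925  (truth: up)

informative fits: 500/500 genes
```

On a simulated 500-gene cohort with a 1.5-SD expression shift, the
derivation recovers all 60 planted signal genes with correct directions;
the weight magnitudes order genes by significance. Scoring the same
cohort (`examples/03_score_samples.py`) separates the fusion groups
completely (AUC 1.000, Wilcoxon p ≈ 3×10⁻²¹), and with a hazard linked
to pathway activity the median-score split yields a log-rank
χ² ≈ 61 (p ≈ 5×10⁻¹⁵) with the high-score group faring worse
(`examples/04_survival_stratification.py`).

The same stages are available as a CLI:

```bash
fusionsig simulate --out-dir cohort/ --seed 1
fusionsig derive   --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
                   --top-k 700 --out signature.tsv
fusionsig score    --expr cohort/expression.tsv --signature signature.tsv \
                   --n-perm 1000 --seed 0 --out scores.tsv
fusionsig evaluate --scores scores.tsv --clinical cohort/clinical.tsv \
                   --out report.json
```

## File formats

| file | format |
| --- | --- |
| expression | TSV (first column `gene`, header of sample ids) or GCT 1.2 |
| clinical | TSV: `sample_id, fusion_status, age, gleason, time, event[, extra numeric columns]`; missing values as `NA`; `fusion_status` ∈ {positive, negative, erg_other} |
| signature | two-column TSV `gene<TAB>weight`, weights in [−1,1]\{0} |
| scores | TSV `sample_id<TAB>score` plus a JSON sidecar with seed/permutation metadata |
| reports, manifests, truth | JSON |

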