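# survscreen

Survival-based screening for prognostic expression features, built the way
it is used in large tumor-cohort transcriptomics: an **iterated
split-sample log-rank screen** with a **permutation-null false discovery
rate**, followed by evaluation of whether a candidate marker adds clinical
value beyond stage and grade (Cox proportional hazards, CHAID decision
trees, time-dependent survival ROC, decision-curve analysis), and a
**knockdown-signature** arm that takes a gene set perturbed in cell lines
back into the tumor cohort.

The package targets analyses like lincRNA biomarker discovery in clear cell
renal cell carcinoma: a cohort of a few hundred tumors with overall-survival
follow-up, several thousand sparsely expressed features (RPKM scale), and
the need to rank features by how *reproducibly* — not just how strongly —
they predict survival.

## The screen

Given an expression matrix `X` (features × samples) and survival data
`(Tᵢ, δᵢ)`, each iteration `b = 1 … B`:

1. randomly splits the cohort into equal-sized discovery and validation
   halves;
2. within the discovery half, dichotomizes each feature at its median and
   computes the Mantel–Haenszel log-rank statistic
   `χ² = (Σⱼ O₁ⱼ − E₁ⱼ)² / Σⱼ Vⱼ` over distinct death times `j`;
3. features with `p < α` (default `α = 0.001`) are re-tested — fresh median,
   fresh log-rank — in the validation half; those with `p < α` in both
   halves are *validated* in iteration `b`.

A feature's **validation frequency** `fₖ = #{b : validated} / B` is the
ranking statistic. A parallel run on label-permuted data (clinical records
dissociated from expression columns, one permutation per iteration) yields
a null distribution of validation frequencies, and

`FDR(c) = E₀[#{k : fₖ ≥ c}] / #{k : fₖ ≥ c}`

estimates the false discovery rate at frequency cutoff `c`.

Everything downstream of the screen — Cox fits with stage/grade/age/sex
coding, CHAID recursive partitioning, IPCW cumulative/dynamic ROC at a
horizon, net-benefit decision curves, ≥1.25-fold knockdown signatures,
hypergeometric overlaps, and average-linkage Pearson clustering of tumors
on a signature — lives behind the same API, and a bundled synthetic-cohort
generator (zero-inflated log-normal expression, exponential
proportional-hazards survival with planted effects, administrative
censoring) makes the whole chain testable without access to controlled
patient data.

## Worked example

The bundled demo simulates a 300-tumor cohort with one planted prognostic
feature (conditional HR 3.5 given stage, grade and age) among 199 nulls,
screens it over 50 random splits, and runs the full downstream analysis:

```sh
survscreen run --config examples/demo_config.yaml
```

`survscreen_demo/screen_result.tsv` then ranks the planted feature first:

```
feature_id  validation_count  validation_frequency  median_discovery_p  rank
LINC000     11                0.22                  0.00058             1
LINC186     0                 0.00                  0.06667             2
```

The planted feature validates in 22% of splits — at n = 300 with active
clinical covariates, the *marginal* median-split effect the unadjusted
log-rank sees is frailty-attenuated well below the planted conditional
HR of 3.5, which is exactly why the screen ranks by reproducibility across
splits instead of by a single p-value. No null feature validates even once
(`fdr.json` reports 0 observed and 0 null features at the 0.5 frequency
cutoff). The CHAID stage prints, for the same run,

```
[n=300, deaths=114 (38%)]
split on stage (adj p=3.99e-10)
  [n=179, deaths=41 (23%)] <- I/II
  split on marker (adj p=0.00438)
    [n=83, deaths=27 (33%)] <- high
    [n=96, deaths=14 (15%)] <- low
  [n=121, deaths=73 (60%)] <- III/IV
  ...
```

i.e. tumor stage dominates, and the screened marker further stratifies risk
within stage strata (33% vs 15% death rate within stages I–II here).

The same stages are importable directly (`survscreen.screen.run_screen`,
`survscreen.utility.compare_models`, `survscreen.signature.*`) for use on
real matrices read with `survscreen.expression.read_matrix` /
`read_clinical`.

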