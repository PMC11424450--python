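# mrscreen

Two-sample Mendelian randomization (MR) gene screening: infer which
genes' blood expression causally influences disease risk from GWAS and
cis-eQTL summary statistics, confirm hits by Bayesian colocalization,
and characterize them with differential-expression, co-expression and
gene-set-enrichment follow-up. Every stage runs on synthetic summary
statistics with known ground truth, so the whole pipeline is testable
without downloading any cohort data.

The package is for statistical geneticists and computational
biologists who want an auditable, seedable implementation of the
standard eQTL→disease screening workflow as a Python library, with a
thin command-line layer for one-shot runs.

## The statistics at the core

For gene *g* with instruments *j = 1…J* (cis-eQTL SNPs surviving FDR
< 0.05, LD clumping at r² = 0.1, and F > 10), the causal effect of
expression on disease is estimated by the inverse-variance-weighted
(IVW) combination of per-SNP Wald ratios:

    β̂_IVW = Σⱼ β̂ₑₓₚ,ⱼ β̂ₒᵤₜ,ⱼ / var(β̂ₒᵤₜ,ⱼ)  ÷  Σⱼ β̂²ₑₓₚ,ⱼ / var(β̂ₒᵤₜ,ⱼ)

with fixed-effect standard error `1/√Σ β̂²ₑₓₚ/var(β̂ₒᵤₜ)`. MR-Egger
regression (free intercept = average directional pleiotropy) and the
weighted median (consistent with up to 50% invalid instruments)
complement it; Cochran's Q, the Egger intercept test, MR-PRESSO and
leave-one-out refits form the sensitivity battery. Survivors of
discovery + replication screening (Benjamini–Hochberg across genes,
per cohort) and reverse MR are tested for a shared causal variant by
Wakefield approximate-Bayes-factor colocalization over the gene
± 500 kb: posterior probabilities of H0 (no association) through H4
(shared variant), with PP.H4 > 0.80 declaring colocalization.

## Worked example

```python
from mrscreen import (MRSimConfig, simulate_instruments, harmonize,
                      ivw, mr_egger, weighted_median)

exposure, outcome, truth = simulate_instruments(
    MRSimConfig(j_snps=40, theta=0.25, seed=11))
h = harmonize(exposure, outcome)
for fit in (ivw(h), mr_egger(h).slope, weighted_median(h, seed=0)):
    print(f"{fit.method:>16}: beta = {fit.estimate:+.3f} "
          f"(se {fit.se:.3f}, p = {fit.pvalue:.2e})")
```

prints

```
             ivw: beta = +0.284 (se 0.021, p = 2.55e-43)
           egger: beta = +0.324 (se 0.038, p = 3.07e-10)
 weighted_median: beta = +0.307 (se 0.030, p = 5.95e-24)
```

— three estimators agreeing with the simulated truth (0.25) within
their uncertainties, on 40 instruments whose effect alleles were
aligned across the two tables by `harmonize`. The scripts in
`examples/` walk through each capability the same way: estimation and
sensitivity analysis, colocalization (a shared-variant region yields
`H4=1.000` and names the right SNP), expression follow-up, and the
end-to-end screen, which on a simulated 20-gene panel flags exactly
the one gene whose expression truly drives disease risk:

```
candidates: ['GENE01'] (truth: ['GENE01'])
```

From the shell, the same stages are available as subcommands:

```bash
mrscreen simulate --kind mr --seed 3 --out-dir sim/
mrscreen mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
            --ld sim/ld.tsv --out mr_results.tsv
mrscreen screen --seed 1 --n-genes 20 --out-dir screen_run/
```

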