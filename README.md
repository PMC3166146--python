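# cissat

Saturation analysis of multi-tissue cis-eQTL detection: how many cis-acting
expression quantitative trait loci does a cohort of a given size reveal, how
does that number scale as the cohort grows, and which detections are shared
between tissues versus tissue-specific?

`cissat` is aimed at statistical geneticists planning or interpreting
multi-tissue eQTL studies. It implements the complete analysis as a tested,
deterministic pipeline:

1. **cis-eQTL calling** per tissue and sample subset — a Kruskal–Wallis rank
   test of expression over the genotype classes {0, 1, 2} for every SNP in
   the cis window (transcription start site ± 1 Mb), a per-subsample minor
   allele frequency filter (MAF must exceed 5%), lead-SNP selection (only
   the smallest-p SNP per transcript is retained, so an eQTL is identified
   with its transcript and its *eSNP* is that lead SNP), and a permutation
   FDR threshold: expression sample labels are shuffled, the full scan
   including lead selection repeated, and the reporting threshold chosen as
   the largest observed p with estimated FDR ≤ 10%.
2. **Nested subsampling** — K sample sizes equally spaced in ln *n* (the
   classic design is 20 steps from 50 up to the full cohort), one nested
   chain N₁ ⊂ … ⊂ N_K per replicate, with the full scan (MAF filter and
   permutation FDR included) re-run at every step, tissue and replicate.
3. **Overlap dynamics** — each detected transcript falls into one of seven
   classes (only A / only B / only C, AB, BC, CA, ABC); between consecutive
   steps the pipeline tracks creation, deletion, move-in and move-out rates
   per class (normalized by Δn), consecutive and reference overlap fractions
   for both eQTL and eSNP sets, per-class distance-to-TSS and association
   strength summaries, and Mann–Whitney contrasts between classes.
4. **Scaling law** — the empirical law √q = α + β ln *n* (q = number of cis
   eQTLs, n = sample size) is fitted by ordinary least squares and inverted
   to extrapolate counts to larger cohorts, q̂(n) = (α + β ln n)², plus
   sliding-window slopes that diagnose saturation versus acceleration.
5. **Synthetic cohort generator** — a three-tissue genotype/expression
   cohort with a known cis architecture (log-normal effect sizes, a
   configurable tissue-sharing pattern in which shared effects are stronger
   and closer to the TSS, first-order linkage disequilibrium), so the whole
   pipeline is testable end to end without any data download. Readers for
   VCF, expression TSV and BED TSS annotation accept compatible real data.

## Worked example

Simulate the default study condition (400 individuals, 2,000 SNPs on a
50 Mb chromosome, 300 transcripts, three tissues) and run one 20-step
saturation series from 50 to 400 individuals:

```python
from cissat import (SimulationConfig, simulate_cohort, run_series,
                    fit_scaling_law, predict_count)

cohort = simulate_cohort(SimulationConfig(seed=1))
result = run_series(cohort, n_min=50, k=20, replicates=1,
                    n_permutations=10, seed=1)[0]
for tissue in cohort.tissues:
    counts = result.counts(tissue)
    fit = fit_scaling_law(result.series.sizes, counts)
    print(f"{tissue}: q(50)={counts[0]:2d}  q(400)={counts[-1]:2d}  "
          f"alpha={fit.alpha:.3f}  beta={fit.beta:.3f}  "
          f"R2={fit.r_squared:.3f}  q_hat(4000)={predict_count(fit, 4000)}")
```

which prints

```
A: q(50)= 9  q(400)=69  alpha=-8.238  beta=2.739  R2=0.945  q_hat(4000)=210
B: q(50)= 4  q(400)=62  alpha=-10.406  beta=3.060  R2=0.938  q_hat(4000)=224
C: q(50)= 1  q(400)=72  alpha=-11.826  beta=3.390  R2=0.960  q_hat(4000)=265
```

Read: at 50 individuals the 10% FDR scan finds 1–9 cis eQTLs per tissue;
at 400 it finds 62–72. The square root of the count is linear in ln *n*
(R² ≥ 0.94 in each tissue), and evaluating the fitted law at a hypothetical
4,000-individual cohort extrapolates to 210–265 detected cis eQTLs — the
saturation curve is nowhere near flat for the pooled count, even though the
tissue-specific classes plateau (run the full pipeline to see the per-class
trajectories).

The same analysis is available from the shell, one stage per subcommand:

```bash
cissat simulate --out cohort/ --seed 1
cissat scan --cohort cohort/ --tissue A --out scan_A.tsv
cissat run --out run/ --seed 1          # simulate + series + dynamics + fit
cissat report --run-dir run/
```

`cissat run` writes every stage as TSV (`manifest.tsv`, `class_counts.tsv`,
`rates.tsv`, `overlaps.tsv`, `specificity.tsv`, `scaling.tsv`, per-scan lead
tables under `runs/`) plus a log; the whole run is reproducible from the one
master seed.

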