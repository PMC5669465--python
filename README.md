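# macrisk

Minor-allele burden analysis and weighted genetic risk scores for
case-control genotype cohorts.

## The problem

A line of work on complex disease asks whether the *collective* load of
minor alleles (MAs) across the genome — not any particular risk locus —
separates cases from controls.  The per-individual statistic is the **minor
allele content**

```
MAC_i = (1 / K_i) * Σ_j  c_ij        over SNPs j with reference-group MAF < 0.4
```

where `c_ij ∈ {0, 1, 2}` counts copies of SNP *j*'s minor allele (the
allele with frequency < 0.5 in a designated reference group) carried by
individual *i*, and `K_i` is the number of those SNPs genotyped in *i*.
Group means are compared with Welch's t-test.  On top of the same
machinery sits a weighted **genetic risk score**

```
GRS_i = Σ_{j ∈ hom} β_j + 0.5 * Σ_{j ∈ het} β_j
```

— the per-SNP log-odds `β_j` from additive logistic regression, counted in
full for homozygous-minor genotypes and in half for heterozygous ones.
Model SNP sets are chosen on a training cohort over a grid of 35
association P-value cutoffs × 6 LD-pruning levels (r² ∈ {0.05, 0.2, 0.4,
0.6, 0.8} in 200-kb windows, plus no pruning; 210 models), scored on a
disjoint validation cohort (AUC with DeLong CI, TPR at 100% specificity,
Nagelkerke R²), cross-checked by internal stratified 5-fold CV, and the
cell best in both rankings wins.  SNPs whose control-defined minor allele
disagrees with the combined-cohort definition ("flips", MAF ≈ 0.5) are
removed from the final model.

The package implements the whole chain — PLINK-text/VCF input, QC (HWE,
missingness, MAF, PCA outliers), LD pruning, association, scoring,
evaluation, model selection — plus a synthetic-cohort generator, since the
cohorts this method was developed on are restricted-access.

## Worked example

```python
import macrisk as mk

# a small cohort with planted polygenic signal biased toward minor alleles
cfg = mk.SimConfig(n_cases=500, n_controls=500, n_snps=1000, n_causal=300,
                   causal_beta_law=("constant", 0.3), p_minor_risk=1.0,
                   seed=50_000)
cohort, truth = mk.simulate_cohort(cfg)
result, comp = mk.mac_case_control(cohort)
print(f"case MAC {comp.case_mean:.4f}  control MAC {comp.control_mean:.4f}  "
      f"t={comp.t:.2f}  p={comp.p:.2e}")
```

prints

```
case MAC 0.4798  control MAC 0.3930  t=32.16  p=3.88e-156
```

cases carry on average 0.48 minor-allele copies per eligible SNP against
0.39 in controls: with 300 strong risk alleles all lying on minor alleles,
case ascertainment concentrates minor-allele burden and the Welch test
detects it overwhelmingly.

The same from the shell:

```bash
macrisk simulate --config sim.cfg --out cohort
macrisk qc --ped cohort --out cohort.qc
macrisk mac --ped cohort.qc --out mac.tsv
macrisk grid --train-ped train --valid-ped valid --seed 1 --out-prefix run
```

`macrisk run-all --config sim.cfg --outdir run/` chains every stage and
leaves each stage's TSV, the serialized best model, and a log in `run/`.

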