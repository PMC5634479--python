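# modemdr

Multiobjective differential-evolution MDR for detecting SNP–SNP
interactions (epistasis) in case–control genotype data.

Complex-disease risk can depend on combinations of loci that show no
single-locus signal. Multifactor dimensionality reduction (MDR) detects
such interactions by pooling the 3^d multi-locus genotype cells of a
d-SNP combination into high/low-risk groups via the training
case:control ratio θ̂_a = (n₊₀·n_a1)/(n₊₁·n_a0) and scoring the resulting
2×2 classifier on held-out folds. `modemdr` searches the combination
space with differential evolution while maximizing **two** MDR measures
simultaneously —

- CCR = ½·(TP/(TP+FN) + TN/(FP+TN)) (balanced accuracy), and
- NMI = (H(y) − H(y|x))/H(y) (normalized mutual information),

returning the Pareto archive of mutually nondominated SNP combinations
instead of a single best model. The package also ships the
penetrance-table simulator used to benchmark detection (Hardy–Weinberg
genotypes, configurable MAF and heritability, including a generator of
*pure* epistatic models with no marginal effects), an exhaustive-search
oracle with cross-validation consistency, and a detection-success-rate
benchmark harness.

Intended users: statistical-genetics researchers studying gene–gene
interaction methods, and anyone needing a reproducible MDR/DE baseline
on simulated case–control panels.

## Worked example

```python
import numpy as np
from modemdr import (MODEConfig, generate_pure_epistatic_model,
                     simulate_dataset, run, chi2_significance,
                     compute_prevalence, compute_heritability)

rng = np.random.default_rng(42)
model = generate_pure_epistatic_model(maf=0.3, h2_target=0.2, rng=rng)
print("prevalence K =", round(compute_prevalence(model), 4))
print("heritability =", round(compute_heritability(model), 4))

ds = simulate_dataset(model, n_cases=200, n_controls=200, n_snps=100,
                      rng=np.random.default_rng(7))
print("planted pair:", ds.functional_indices)

archive = run(ds.data, MODEConfig(pop_size=50, gen_size=100, seed=11))
for m in archive.members:
    p = chi2_significance(ds.data, m.params)
    print(f"{m.key}  CCR={m.fitness.ccr:.3f}  NMI={m.fitness.nmi:.3f}  p={p:.2e}")
```

prints

```
prevalence K = 0.435
heritability = 0.2
planted pair: (66, 67)
(66, 67)  CCR=0.723  NMI=0.168  p=4.71e-19
```

The simulator built a two-locus model with no marginal effects
(prevalence 0.435, heritability exactly 0.2), hid the interacting pair at
random columns 66 and 67 among 98 null SNPs, and the search returned an
archive whose single nondominated member is exactly that pair: its
cross-validated balanced accuracy is 0.723 (chance is 0.5), it removes
16.8% of the outcome uncertainty, and the pooled high/low χ² p-value is
4.7·10⁻¹⁹. On pure models the two objectives are strongly concordant, so
final archives are typically small (one to a handful of pairs).

The same workflow is available from the shell:

```sh
modemdr simulate --maf 0.3 --h2 0.2 --snps 100 --seed 42 --out-dir sim/
modemdr run --input sim/replicate_000.txt --seed 11 --out archive.json
modemdr benchmark --grid grid.json --replicates 20 --methods modemdr,mdr_cvc3 --out rates.csv
```

All outputs are deterministic given `--seed` (byte-identical JSON on
repeat runs).

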