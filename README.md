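# torpormir

Analysis toolkit for cross-species miRNA microarray comparisons of
hibernation-torpor versus active brain samples, and for the downstream
quantification arithmetic such studies rely on.

Mammalian hibernators tolerate levels of brain blood flow that would kill a
non-hibernator, and miRNA regulation is one candidate mechanism. Profiling
a hibernator on a multi-species miRNA chip poses a specific statistical
problem: most probes target other species, so the majority of measurements
sit near the background and fold changes computed naively on them are
meaningless. This package implements the pipeline that deals with that:

- **System-noise estimation** — the noise floor ν is the lowest mean
  expression at which the LOWESS fit of CV ~ mean (CV = sd/μ per probe,
  across all samples) turns from non-linear to linear, found as the start
  of the longest terminal run of the fitted curve with stable slope.
- **Filtering and flooring** — probes with no value strictly above ν are
  non-informative and excluded; remaining values below ν are floored to ν.
- **Signed fold selection** — per probe, fold = +μ_LH/μ_ACR if LH ≥ ACR
  else −μ_ACR/μ_LH (negative = lower in torpor); probes with
  |fold| ≥ 1.25 are selected.
- **Family analysis** — selected probes are grouped regardless of species
  by parent miRNA family (`hsa-miR-200b-3p` → `miR-200`), with up/down
  counts, sign-concordance and extreme fold per family, plus the stacked
  bar-chart summary.
- **Assay arithmetic** — comparative-Ct qPCR ratios (2^−ΔΔCt against a
  miR-103 reference), β-actin-normalized densitometry relative to a
  baseline group, WST-1 viability (A450 − A690 as % of control),
  firefly/Renilla reporter ratios, and the two-tailed two-sample t-test.
- **Seed scanning** — canonical 6mer/7mer-A1/7mer-m8/8mer seed-match site
  detection in target sequences, with the ULM reporter-insert sequences
  bundled as a FASTA fixture.
- **Synthetic data** — a generator producing expression matrices with a
  heteroscedastic noise floor and planted family-coherent effects, plus
  Ct/densitometry/absorbance/luminescence tables with known truth, so
  every stage is verifiable without external downloads.

## Worked example

```python
from torpormir import (ArrayConfig, generate_array, estimate_noise_floor,
                       differential_table, summarize_families)

cfg = ArrayConfig(n_probes=2000, noise_floor=50.0, seed=1,
                  planted_families=(("miR-200", -3.0), ("miR-182", 3.0)))
matrix, truth = generate_array(cfg)

model = estimate_noise_floor(matrix)
print(f"estimated noise floor: {model.noise_floor:.1f} (true 50.0)")

result = differential_table(matrix, model.noise_floor)
print("accounting:", result.accounting)

fams = summarize_families(result.records[result.records["selected"]])
print(fams.head(3)[["family", "n_members", "n_up", "n_down",
                    "concordant", "extreme_fold"]])
```

prints

```
estimated noise floor: 53.6 (true 50.0)
accounting: {'total': 2000, 'excluded': 1101, 'kept': 899, 'selected': 13, 'up': 7, 'down': 6}
    family  n_members  n_up  n_down  concordant  extreme_fold
0  miR-182          3     3       0        True      3.217486
1  miR-200          3     0       3        True     -3.523309
2   miR-11          1     0       1        True     -1.262574
```

The floor is recovered near its planted value; the accounting partitions
the 2,000 probes into excluded background and informative probes; both
planted families are recovered with the correct direction (miR-200 down in
torpor, miR-182 up in this configuration) and internally concordant signs,
while background probes contribute only a handful of false selections near
the 1.25 threshold.

The same chain is available from the shell:

```sh
torpormir simulate array --n-probes 2000 --seed 1 --plant "miR-200:-3.0" --out sim/
torpormir noise --matrix sim/matrix.tsv --samples sim/samples.tsv --out noise.json
torpormir diff --matrix sim/matrix.tsv --samples sim/samples.tsv --noise-model noise.json
torpormir families --diff differential.tsv --plot bars.png
torpormir run-all --config config.yaml       # the whole pipeline + manifest
```

plus `simulate qpcr|assays`, `qpcr`, `densitometry`, `viability`,
`reporter` and `seedscan` subcommands.

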