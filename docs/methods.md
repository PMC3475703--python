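# Methods

`torpormir` implements the analysis chain used for cross-species miRNA
microarray comparisons of hibernation-torpor (LH) versus active (ACR) brain
samples, together with the downstream wet-lab quantification arithmetic and
a canonical seed-match target scanner. This note records the model behind
each stage, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## System-noise estimation (`torpormir.noise`)

**Model.** On a multi-species chip most probes have no true hybridization
partner in the sample, so low-intensity measurements are dominated by an
additive background. For each probe the coefficient of variation
CV = sd/mean is computed across all samples pooled (sd with denominator
n−1). Background-dominated probes show CV rising steeply as the mean falls
(approximately CV ≈ b/μ for additive noise with scale b), while
well-measured probes show a roughly constant multiplicative CV. The system
noise ν is defined as the lowest mean at which the LOWESS fit of CV against
mean becomes linear, i.e. the start of the flat regime.

**Procedure.**

1. CV is fit by LOWESS against log-mean (natural log; log-abscissa
   stabilizes the fit across three decades of intensity), evaluated on a
   `grid_size`-point grid equally spaced in log-mean between the 1st and
   99th percentiles of probe means. Probes with mean = 0 (CV undefined) or
   sd = 0 (no noise information) are excluded from the fit but still pass
   through the filter stage.
2. Local slopes of the fitted curve are central finite differences against
   log-mean. The **linear suffix** is the longest terminal run of grid
   points whose slopes all lie within ±τ·max|slope| of the run's own median
   slope (plus a ~1e−12 absolute epsilon so an exactly flat curve counts as
   fully linear). The run must cover at least `min_suffix_fraction` of the
   grid; otherwise a "no linear regime" error tells the caller to widen τ
   or inspect the scatter — this is the expected outcome on an
   all-background array, which has no flat regime.
3. ν is the grid mean at the start of the suffix, snapped up to the nearest
   observed probe mean (the "lowest observed" value); the snapped value is
   what the filter and flooring stages use.

**Defaults and why.** `grid_size = 200`, `slope_tolerance τ = 0.1` and
`min_suffix_fraction = 0.25` give a deterministic, oracle-checkable rule
(on small grids the suffix equals an exhaustive search over all terminal
runs). `lowess_frac = 0.15`: with heavier smoothing (e.g. 0.3) the local
window around the changepoint spans much of the transition region, the
fitted slope settles only well above the true floor, and the detected
changepoint overshoots by 30–45% on 2,000-probe arrays; at 0.15 the median
estimate sits within ~7–14% of the planted floor across 1,000–20,180
probes while the curve remains smooth enough for stable slopes. All four
are exposed in the config.

**Invariances.** Scaling all intensities by k > 0 scales ν by exactly k
(CV is scale-free, the mean axis scales); permuting sample columns changes
nothing.

## Filtering, flooring and fold selection (`torpormir.differential`)

- A probe is **informative** iff at least one value across all samples is
  strictly greater than ν (strict ">", so a probe sitting exactly at the
  floor is excluded). Kept and excluded sets always partition the input.
- Remaining values below ν are **floored** to ν (idempotent; never
  decreases a value). Because the filter is strict and flooring only lifts
  sub-floor values to ν, filtering commutes with flooring.
- Group means are arithmetic means of floored linear-scale intensities.
  The **signed fold** is +LH/ACR when LH ≥ ACR and −ACR/LH otherwise
  (negative = lower during torpor), +1 at exact equality; its magnitude is
  always ≥ 1 and it is antisymmetric under swapping the groups away from
  ties. The threshold ("absolute mean difference ≥ 1.25") is read as a
  fold-ratio magnitude, inclusive at the boundary; selection is monotone in
  the threshold. Selection is fold-only — no p-value or multiple-testing
  stage belongs to this chain (the t-test applies to the wet-lab assay
  tables).

## Family grouping (`torpormir.families`)

Parent families are parsed from miRBase-style names case-insensitively by
stripping, in order: a 3–4-letter species prefix, the lettered variant, a
duplicate-locus numeric suffix, the −3p/−5p arm (or legacy `*`), e.g.
`hsa-miR-200b-3p → miR-200`, `mmu-let-7f-2 → let-7`. Unparseable names map
to `UNKNOWN` and are reported rather than dropped. Members are counted per
probe (per-species entries), which is how one family can have dozens of
members on a 131-species chip. Per family the summary reports up/down
counts, the concordance flag (all member folds sharing one sign), and the
extreme fold (maximal magnitude, a tie resolving to the positive sign),
with the mean fold emitted alongside. Name-based grouping is the default;
a broader seed-based family (e.g. miR-141/miR-429 under miR-200) can be
imposed only through an explicit `family_map` table, never inferred from
sequence.

Because the original selected-miRNA list is not redistributable, the
package ships a deterministic **synthetic stand-in**
(`synthetic_family_table`) whose raw (name, fold) rows encode the published
summary structure — 405 entries, 33 parsed families, the largest family
(miR-200) with 48 members and extreme fold −3.04, exactly one discordant
family (miR-125) — so the parser and summarizer can be exercised end to
end. Tests on it demonstrate the machinery, not the original data.

## Assay arithmetic (`torpormir.assays`)

- **2^−ΔΔCt**: ΔCt(g) = mean Ct(target, g) − mean Ct(reference, g) with
  miR-103 as the default reference (stably expressed across the
  hibernation bout); ΔΔCt = ΔCt(test) − ΔCt(baseline); ratio = 2^−ΔΔCt.
  Group means of per-sample Ct are taken before differencing; per-sample
  ratios are also emitted for dispersion estimates. No
  amplification-efficiency correction (pure comparative-Ct method).
  Reversing test and baseline inverts the ratio exactly.
- **Densitometry**: lane ratio = (target band / β-actin band) divided by
  the baseline-group mean of the same quantity, so the baseline group has
  mean 1 by construction and any common per-lane scale cancels.
- **WST-1 viability**: 100·(A450 − A690)/control corrected absorbance.
- **Dual-luciferase**: 100·(firefly/Renilla)/control ratio.
- **t-test**: classical pooled-variance two-tailed two-sample t by default
  (Welch by flag). Two identical zero-variance groups return t = 0, p = 1,
  flagged degenerate.

## Seed scanner (`torpormir.seedscan`)

Canonical site classes by strict Watson–Crick complementarity to miRNA
positions 2–7 (the seed): 6mer core; 7mer-m8 adds the complement of
position 8 immediately 5' of the core on the target; 7mer-A1 adds an A
opposite position 1 immediately 3' of it (an A regardless of position 1's
identity); 8mer adds both. Coordinates are 0-based half-open on the given
strand; DNA and RNA are accepted (T ≡ U); overlapping sites are all
reported, each at its maximal class; G:U wobble is off by default
(configurable). This deterministic scanner deliberately replaces
free-energy/hybridization scoring: it is exactly checkable against
brute-force window enumeration, and raising the minimum class can only
shrink the site list. The reporter-insert sequences used in the ULM
(SUMO-1/3, UBE2I, NEDD8, UFM1) 3'UTR reporter assays ship as a bundled
FASTA fixture; mature miRNA sequences are user-supplied.

## Synthetic data (`torpormir.synthetic`)

The generator emulates the statistical structure the pipeline assumes, with
full ground truth:

- **Intensities**: value = max(ε, Normal(μ, sd(μ))) with
  sd(μ) = max(background_sd, cv_above_floor·μ) and ε = 1e−6. The max() of
  an additive background scale and a multiplicative term puts an exact
  changepoint in the CV~mean curve at ν = background_sd/cv_above_floor;
  `background_sd` defaults to cv_above_floor·ν_true so the changepoint sits
  exactly at the configured floor. (A sum of lognormal signal and additive
  background was considered and rejected: its CV~mean curve dips below its
  asymptote and has no well-defined changepoint.)
- **Probe means**: expressed probes (fraction 0.5 by default) draw true
  means log-uniform in [0.6, 100]·ν, so the hyperbolic CV branch is
  populated right up to the floor; unexpressed probes sit at per-probe
  background levels log-uniform in [0.1, 0.6]·ν — sub-floor by
  construction, so an all-background array is almost entirely removed by
  the filter. Planted differential families are always expressed, with ACR
  means log-uniform in [4, 40]·ν and the signed fold applied to the LH
  mean (negative = lower in LH); every planted family is guaranteed at
  least `min_planted_members` members.
- **Names**: probe ids follow miRBase style
  `<species>-miR-<N><letter>[-locus][-arm]` over 131 synthetic species
  codes, with collisions resolved by duplicate-locus suffixes, so family
  parsing is exercised realistically. Scale defaults (20,180 probes, 131
  species, 6 vs 6) mirror the targeted study design; simulations and tests
  run at 1,000–5,000 probes, which keeps the whole suite in seconds while
  leaving every estimator comfortably determined.
- **Assay tables**: Ct tables are built so 2^−ΔΔCt recovers the configured
  ratios exactly at zero noise (reference flat across groups); likewise
  densitometry/absorbance/luminescence tables encode known ratios,
  viability fractions and reporter fractions. All randomness flows from one
  `numpy` generator per call — same config, same bits.

**What the generator does not emulate**: probe-set summarization and
normalization artifacts, inter-array batch effects, sequence-driven
cross-hybridization (family members are labels, not sequences),
non-Gaussian outliers, and spatial array defects. Passing tests therefore
show the analysis logic is correct under the stated noise model, not that
the model captures every feature of real chips.

## Numerical notes and edge cases

- LOWESS evaluation uses `statsmodels` with interpolation at grid points;
  the fit requires ≥ 50 probes with defined CV.
- The changepoint search is O(grid²) with exact median recomputation per
  suffix — negligible at grid_size 200 and directly comparable to the
  exhaustive oracle.
- `fold_difference` rejects non-positive means (flooring guarantees
  positivity upstream).
- Degenerate inputs: all-equal matrices (CV ≡ 0) yield a fully linear
  curve and ν at the grid minimum; empty selections produce an empty family
  table and a placeholder figure, not an error.

## Known limitations

- The floor estimator retains a small positive bias (~+10% at default
  settings) because smoothing is one-sided around the changepoint; the
  snapped "lowest observed mean ≥ changepoint" convention adds a
  negligible further upward nudge.
- Name-based families treat e.g. miR-141 and miR-429 as separate families;
  merging them requires an explicit map.
- The scanner reports complementarity, not repression efficacy: no
  free-energy model, conservation filter, or 3'-supplementary pairing.
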