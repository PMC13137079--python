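# Methods

## Model

A KASP reaction reads two fluorescence intensities, FAM and HEX, each
reporting one allele of a species-diagnostic biallelic SNP. In the
(FAM, HEX) plane, a signal's useful information is almost entirely angular:
the angle α from the origin (0° along FAM, 90° along HEX) encodes the ratio
of the two allele-specific amplifications, while the radius mostly reflects
template amount and reaction efficiency. `kasphi` therefore reduces every
averaged signal to its angle and calibrates the angle scale per SNP.

Three genotype clusters anchor the calibration: A (homozygous for the
HEX-reported allele), AB (heterozygous) and B (homozygous for the
FAM-reported allele). Ideally α_A = 90°, α_AB = 45°, α_B = 0°; in practice
residual off-channel fluorescence pulls the homozygote angles inward and
unequal primer competition displaces α_AB differently for every SNP. Using
the *measured* centroid angles as anchors absorbs both artefacts. The
hybrid index is then the piecewise-linear map with HI(α_A) = 0,
HI(α_AB) = 0.5, HI(α_B) = 1, linearly extrapolated outside [α_B, α_A]
(no truncation — truncating would bias population averages toward the
interior). The map is continuous and strictly decreasing; its inverse is
used by the simulator.

An individual's genotype contributes HI ∈ {0, 0.5, 1} (A/AB/B); a
population's expected HI is the mean over members, and an eDNA sample's
observed HI is the mean of its per-SNP estimates.

## Pipeline order and quality control

1. **Read-cycle selection.** PCR plates are read at several cycle counts
   (39–51 in the reference design). Excess cycles breed primer dimers,
   which show up as fluorescence in no-template and water controls. The
   rule: pick the largest candidate cycle at which no NTC/lab-negative
   reading escapes the low-fluorescence triangle; if all cycles show such
   signal, fall back to the smallest with a warning. Selection is
   plate-level (controls are laid out per plate); a per-SNP run simply
   passes a subset.
2. **Low-fluorescence exclusion.** Any reaction inside the triangle with
   vertices (0,0), (2,0), (0,2) — boundary inclusive, the conservative
   choice for a noise floor — is removed before averaging.
3. **Replicate averaging.** Arithmetic mean of FAM and HEX over the
   retained replicates per sample × SNP (mean, not median: with ≤4
   replicates a median would discard information and the low-signal filter
   has already removed the gross failures).
4. **Genotype verification.** Per SNP, class centroids are component-wise
   (marginal) medians of the averaged swab signals — "median fluorescence"
   taken per channel; the marginal median is cheap, robust and axis-aligned
   with the quantities actually measured. A swab call nearer a different
   centroid than expected is a mismatched genotype; exact distance ties are
   treated as mismatches (an ambiguous call validates nothing). A mismatch
   excludes the swab call *and* the eDNA calls at that SNP for every
   population housing the animal; an animal mismatched at all its typed
   SNPs is presumed mislabelled and excluded entirely together with its
   containers.
5. **Outlier screening.** Within each (SNP, genotype) cluster, distances to
   the assigned centroid are screened at median + 3 × MAD, with
   MAD = 1.4826 · median(|d − median(d)|) (the normal-consistency constant;
   both the multiplier and the constant are configurable and logged).
   Mismatch flagging deliberately uses the pre-exclusion centroids and the
   outlier screen runs on the mismatch-cleaned set, keeping the two
   exclusion mechanisms separately accountable.
6. **Angle extraction.** Centroids are recomputed from the retained points
   before angles are taken, so the anchors reflect the cleaned clusters.
   The ordering α_B < α_AB < α_A is enforced; a violating SNP is unusable.

Degenerate branches: a singleton cluster is never excluded (MAD undefined,
warning); a zero-MAD cluster excludes only points strictly above the median
distance — the literal "≥" rule would void an entirely tied cluster.

## Validation statistics

Deviations HI_obs − HI_exp are not normal in this kind of data, so the
battery is non-parametric:

- **Per-SNP bias screen** — median swab deviation per SNP with a percentile
  bootstrap 95% CI (B = 2000, seeded); a SNP is retained only when the
  whole CI lies within ±0.05 HI units (5% of scale).
- **Concordance** — Spearman rank correlation per sampling regime, average
  ranks for ties; exact permutation p by full enumeration for n ≤ 8, the
  t-approximation above. (Full enumeration beyond n = 8 costs ≥ 360k
  permutations for no practical gain at these sample sizes.)
- **Regime effect** — permutation ANCOVA HI_obs ~ HI_exp × regime with
  Freedman–Lane residual permutation (default 5000 permutations): for each
  term the reduced model's residuals are permuted, added back to the
  reduced fit, and the partial F recomputed; p = (1 + #{F* ≥ F}) /
  (n_perm + 1). Implemented via QR projections, vectorised across
  permutations.
- **Profile bias** — Kruskal–Wallis across genotypic profiles per regime;
  per-profile one-sample Wilcoxon signed-rank vs 0 with Holm correction
  within regime. Wilcoxon uses the zero-discard rule, exact distribution
  for n ≤ 25 without ties, normal approximation with continuity correction
  otherwise; an all-zero profile is degenerate and reported as p = 1.
  Inputs are per sample–SNP deviations by default (matching how the
  per-profile distributions are defined); population-level input just
  means passing the aggregate table instead.
- **Variance homogeneity** — pairwise Fligner–Killeen across profiles,
  Holm-adjusted as one family; constant groups are untestable and excluded
  from the family.
- **Agreement** — Bland–Altman mean bias and 95% limits of agreement
  (mean ± 1.96 SD, sample SD with n − 1 denominator), applied to
  per-population deviations within each regime and to per-population
  differences between regimes (low − high).
- **Biomass correction** — expected HI reweighted by body mass,
  Σ m_i·hi_i / Σ m_i; for mixed-genotype profiles, |deviation| under
  uncorrected vs corrected expectation compared by paired Wilcoxon, Holm
  across profiles.

Holm adjustment is statsmodels' step-down implementation; NaN (untestable)
entries pass through unadjusted.

## Simulator

The generator emulates the mesocosm validation design. Defaults are the
study conditions; every one is a `SimConfig` field.

| parameter | default | meaning |
|---|---|---|
| `n_snps` | 9 | species-diagnostic SNP panel size |
| `alpha_a_mean/sd` | 82.0° / 1.13° | true α_A distribution across SNPs |
| `alpha_ab_mean/sd` | 46.6° / 6.05° | true α_AB distribution (primer competition) |
| `alpha_b_mean/sd` | 12.9° / 1.46° | true α_B distribution |
| `radius_median`, `radius_log_sd` | 3.0, 0.15 | lognormal fluorescence magnitude |
| `swab_angle_sd` | 2.0° | within-cluster angular noise, swab arm |
| `edna_angle_sd` | 4.0° | angular noise, eDNA arm (less template → noisier) |
| `regime_noise_scale` | low 1.25 / high 1.0 | regime multiplier (~35% lower variance at high concentration, i.e. SD ratio ≈ 1.25) |
| `dropout_rate` | 0.035 | heterozygote call renders at a random homozygote angle |
| `false_het_rate` | 0.0127 | homozygote call renders at the heterozygote angle |
| `low_signal_rate` | 0.045 | reaction lands uniformly in the noise triangle |
| `shedding_concentration` | 5.0 | Dirichlet concentration of per-individual shedding weights (`inf` = exactly equal shedding) |
| `replicates` | 4 | PCR replicates per sample × SNP |
| `profile_replicates` | 3/3/6/3/3 | populations per profile {0, 0.25, 0.5, 0.75, 1} |

Angular noise SDs are not directly observable from printed summaries; 2°
(swab) and 4° (eDNA) were chosen once as values that put per-call HI noise
in the few-percent range a clean KASP assay achieves, and are not tuned.
The shedding concentration of 5 gives two-animal weight SDs of ≈0.15 —
noticeably unequal individual contributions without letting one animal
dominate.

Mechanics worth knowing:

- Error modes act at the call (animal × SNP) level — allelic dropout is a
  template-level failure, so all four replicates of an affected call render
  at the wrong angle; low-signal failures strike single reactions.
- Per eDNA sampling event, one Dirichlet weight vector is shared across
  SNPs (the same individuals shed for all loci), which induces the
  across-SNP correlation that makes population-level deviations wider for
  mixed profiles.
- A profile 0.5 population of two F1 hybrids is *insensitive* to shedding
  inequality (every member contributes HI 0.5), so shedding-driven variance
  inflation appears only in the 0.25 and 0.75 profiles. Any extra variance
  of the 0.5 profile in real data must come from other sources (e.g.
  allele-specific amplification competition), which the generator does not
  model.
- Angles are clipped to [0°, 90°] after noise (intensities cannot be
  negative), and latent eDNA proportions pass through the inverse HI map of
  each SNP's true calibration.

What the simulator does **not** emulate: systematic channel asymmetries
(the real data's directional bias toward one species at mixed profiles),
PCR inhibition, cross-contamination, temporal eDNA accumulation or decay,
and multi-cycle read series (it emits the selected read cycle only, as an
already-cycle-selected table; the cycle-selection rule is exercised with
constructed control layouts). Passing tests on simulated data therefore
demonstrate internal consistency and statistical calibration of the
pipeline, not field performance.

## Problem sizes

The test suite and acceptance script run, as the package's own choices: the
default 18-population layout for design counts and pipeline smoke paths; a
120-container layout (240 population samples) for recovery accuracy (RMSE
≤ 0.1, |bias| ≤ 0.05 at default noise; exact recovery in the zero-noise
limit); 1000-replicate null simulations for type-I-error calibration of
the permutation ANCOVA and the Holm-corrected Wilcoxon battery (nominal
0.05 within 3 Monte-Carlo SE); 100 containers per profile for the
shedding-variance pattern; and 1000 random instances per primitive for
oracle cross-checks against naive reference implementations.

## Known limitations

- The hybrid index aggregates allele proportions; it cannot distinguish a
  hybrid population from syntopic pure species at a single locus, nor
  resolve hybrid classes (F1/F2/backcross).
- Centroid calibration needs all three genotype classes present per SNP in
  the swab arm; panels missing a class for some SNP fail calibration for
  that SNP rather than guessing.
- The regime comparison assumes the same populations are sampled under
  both regimes (paired design); unpaired designs only lose the
  between-regime Bland–Altman.
- Exact Spearman p-values are enumerated only for n ≤ 8.
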