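# Methods

This note documents the models, conventions and numerical choices behind
`exoscreen`, and what the synthetic-data generator does and does not
emulate.

## The screen being analysed

The pipeline targets supplementation screens of a phototroph in which
each culture condition is one (metabolite, concentration) pair plus one
unsupplemented control — by default 32 metabolites × {100 µM, 5 mM} + 1
control = 65 conditions, three biological replicates each, cultures
inoculated at OD₇₅₀ = 0.01 and grown for 10 days. Three sample classes
are measured by negative-mode LC-MS: day-10 culture supernatants,
uninoculated background medium, and sterile supplemented-medium
references (one set per supplemented condition). Five panel compounds
(urea, trimethylamine, methanol, ammonia, acetate) ionize poorly in
negative mode; they carry an `unmeasurable` flag in the design and are
excluded from consumption analysis, leaving 27 metabolites eligible.

## Growth analysis

Final growth is the day-10 OD₇₅₀ (mean ± sample SD over replicates).
The classifier runs a two-sided Welch's *t* test of each condition's
replicate finals against the control's:

t = (x̄_a − x̄_b) / √(s²_a/n_a + s²_b/n_b), df per Welch–Satterthwaite.

Decision rule, in order: mean final OD below the no-growth threshold
(default 0.05, i.e. 5× the inoculum — the threshold is absolute and
should be rescaled with the inoculum) ⇒ *complete_inhibition*; else
*P* < α (default 0.05) with mean above/below control ⇒
*enhanced*/*inhibited*; else *none*. No multiple-testing correction is
applied by default, mirroring per-condition screening practice; a
Benjamini–Hochberg option exists for reuse. Degenerate inputs follow
fixed conventions: two constant groups with equal means give *P* = 1,
with different means *P* = 0 (difference beyond measurement resolution).
Constant groups are detected by zero range, not zero variance, because
the variance of *n* identical floats can round to ~10⁻³².

The exponential-phase diagnostic regresses ln(OD) on time over days 0–4
(endpoints inclusive, points as sampled, no interpolation); non-positive
ODs are excluded and flagged, and windows with fewer than two usable
points or flat curves report R² = 0 with a flag rather than NaN.

## Exact-mass annotation

Ions are treated as singly deprotonated [M−H]⁻ (the only adduct
modelled; acquisition is negative-mode and no adduct list is assumed),
so the neutral mass is M = m/z·z + z·1.007276 Da. Every metabolite whose
neutral monoisotopic mass lies within the ppm tolerance (default 10 ppm,
relative to the metabolite mass) matches; multiple matches produce one
ambiguous label with names sorted and '/'-joined, which keeps annotation
independent of input ordering. Unmatched ions are retained as
unannotated features. When several ions match one metabolite, downstream
analyses use the ion with the largest total intensity across samples
(ties broken by ion id).

## Exometabolome normalization

Per annotated metabolite, in this order:

1. **LOD**: µ_bg + 3σ_bg over background-medium samples (sample SD,
   n−1 denominator; at least two background samples required).
2. **Below-LOD reassignment**: supernatant intensities below the LOD are
   set to µ_bg.
3. **Supplement masking**: in the conditions where the metabolite itself
   was supplemented, its intensity is set to µ_bg, so leftover
   supplement cannot appear as exudation.
4. **Scaling**: (I − µ_bg) / (I_max − µ_bg), clipped to [0, 1], where
   I_max is the maximum post-masking intensity over individual
   supernatant samples (not condition means). If I_max ≤ LOD the
   metabolite is never produced and all its values are 0.
5. **Averaging**: replicate values are averaged per condition *after*
   scaling.

Only day-10 supernatant samples enter the scaling; background samples
define the zero of the scale and sterile references exist solely for
consumption calls. Per-cell provenance flags record `measured`,
`below_lod_reassigned` (all replicates below LOD) or
`supplement_masked`; masked cells are exactly 0.

## Consumption / mixotrophy calls

For each measurable supplemented condition, fraction consumed =
max(0, 1 − mean(day-10 supernatant)/mean(sterile reference)) on the
supplement's ion, with a Welch test between the two replicate groups.
The sterile supplemented-medium reference is the drawdown baseline
(day-0 culture supernatants are typically not sampled in this design).
A call requires a reduction of at least 10% *and* *P* < 0.05; a
metabolite is mixotrophic overall when called at either concentration.

## Exudate ranking and pathway scores

Metabolites are ranked by normalized intensity summed over all
conditions (ties broken lexicographically);
`n_producing_conditions` counts conditions with value > 0. The pathway
importance score of pathway *p* in condition *c* is
(number of produced metabolites belonging to *p*) / (number of distinct
produced metabolites mapping to ≥ 1 pathway in *c*); a metabolite in *k*
pathways counts in each numerator but once in the denominator, keeping
scores in [0, 1]. A multiplicity-weighted denominator (sum of
per-pathway counts) is available behind a flag. "Produced" means
normalized value > 0, i.e. above LOD after masking; the threshold is
exposed. Conditions with no produced pathway-mapped metabolite get
undefined (NaN) scores with a flag rather than zeros.

## PCA

Rows are condition profiles (replicate means), columns metabolites;
columns are mean-centered but not variance-scaled, since normalized
values already share the [0, 1] scale. Conditions classified
complete-inhibition are excluded (no culture, no exometabolome). The
decomposition uses the full SVD; sign indeterminacy is resolved by
making the largest-magnitude loading of each component positive, which
makes results reproducible across runs and BLAS builds. Top-k loading
extraction returns the k most positive and k most negative loadings
ordered by magnitude (ties by metabolite id); only strictly
positive/negative loadings qualify, with a warning when a list is
truncated.

## Synthetic-data generator

The generator emulates the *processed* data level only — design table,
OD₇₅₀ curves, ion × sample feature matrix — never raw spectra,
retention times or chromatographic peaks.

- **Growth**: logistic curves with shared rate (0.8 day⁻¹), shared
  start OD 0.01 and condition-specific carrying capacity (control 1.0;
  enhanced/inhibited multiply it, default 1.5×/0.5×;
  complete-inhibition pins capacity at the inoculum). Logistic is the
  simplest model with an exponential early phase and a plateau. OD noise
  is additive Gaussian with SD = cv·OD.
- **Intensities**: per-ion baselines are log-uniform in [10², 10³];
  sterile references carry the supplement ion at 20 counts/µM (2×10³ at
  100 µM, 10⁵ at 5 mM); day-10 supernatants show the supplement at
  level·(1 − drawdown), floored at baseline, and planted exudates at
  baseline·fold (default 10×). Isobaric metabolites share a single ion
  (feature alignment cannot separate identical exact masses);
  overlapping contributions combine by max. Measurement noise is
  mean-preserving multiplicative log-normal with the configured CV;
  `noise_cv = 0` yields noiseless output used by exact closure tests.
  The default CV of 5% is a generator choice representative of
  well-behaved LC-MS replicates; within-replicate CV is not a quantity
  the pipeline itself estimates.
- **Default scenario** (`paper_like_config`): 7 enhancers (capacity
  folds 1.10–1.53), 36 inhibitors of which 15 lethal (12 at 5 mM, 3 at
  100 µM), 15 consumed metabolites (drawdown 0.30–0.86), three broadly
  exuded stress metabolites, and two condition-specific 5-metabolite
  exudation signatures (a glucose-like and a valine-like response).
- **Not simulated**: evaporation/replenishment dilution (folded into
  noise), ion suppression, retention-time information, adducts other
  than [M−H]⁻, missing values (all cells are explicit positive
  numbers).

Because planted effects enter as clean multiplicative signals with
independent log-normal noise, passing recovery tests demonstrates the
pipeline's logic and calibration — not robustness to batch effects,
drift, or correlated noise found in real screens.

## Determinism and problem sizes

A single master seed drives per-stage `numpy` Generator streams, so
identical configs give bit-identical outputs, and `run-all` writes a
manifest with parameters and input SHA-256 hashes. The verification
studies use 10,000 null simulations for Welch calibration, 200 seeded
runs per arm for drawdown-call rates, 20 seeds for PCA signature
recovery, and a full 65-condition × 1000-ion screen for the end-to-end
closure — sizes chosen to make the measured rates stable to within a
percentage point or two while keeping the whole suite fast.
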