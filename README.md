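# exoscreen

Analysis pipeline for high-throughput **nutrient-supplementation screens
of phototrophs**: given OD₇₅₀ growth curves and an untargeted LC-MS
feature table of culture supernatants, it classifies growth effects,
normalizes the exometabolome, calls mixotrophic substrate consumption,
ranks exudates, scores metabolic-pathway importance and profiles
conditions by PCA.

The intended user is a microbial physiologist running a screen of the
form *32 supplements × {100 µM, 5 mM} + control, in triplicate*: a
cyanobacterium (e.g. *Synechocystis* sp. PCC 6803) grown for 10 days
under each condition, with day-10 cell-free supernatants, uninoculated
background medium (BG-11) and sterile supplemented-medium references
measured by negative-mode LC-QTOF-MS. A synthetic-data generator with
planted ground truth (growth effects, drawdown fractions, exudation
signatures) stands in for deposited raw data and makes every stage
testable.

## Methods at a glance

- **Growth effects.** Per condition, day-10 OD₇₅₀ replicates are compared
  to the unsupplemented control with a two-sided Welch's *t* test
  (unequal variances, Welch–Satterthwaite df). A condition is *enhanced*
  or *inhibited* when *P* < 0.05 with the corresponding direction, and
  *complete inhibition* when mean final OD < 0.05 (5× the 0.01 inoculum).
  An exponential-phase check reports R² of ln(OD) vs *t* over days 0–4.
- **Annotation.** Ions are assumed singly deprotonated [M−H]⁻, so
  *M* = *m/z* + 1.007276 Da; all metabolites within 10 ppm match, and
  isobars (leucine/isoleucine, glucose/fructose) collapse into one
  ambiguous label.
- **Exometabolome normalization.** Per metabolite: LOD = µ_bg + 3σ_bg
  over background-medium samples; intensities below LOD are reassigned
  to µ_bg; the metabolite's own intensity is masked to µ_bg in the
  conditions where it was supplemented; then values are scaled to
  (I − µ_bg)/(I_max − µ_bg) ∈ [0, 1], with I_max the highest
  post-masking supernatant sample, and replicates averaged per condition.
- **Mixotrophy.** fraction consumed = max(0, 1 − Ī_day10/Ī_reference);
  a metabolite is consumed at a concentration when the reduction is ≥ 10%
  and significant (Welch *P* < 0.05), and mixotrophic overall when the
  call holds at either concentration.
- **Exudate ranking.** Metabolites ranked by summed normalized intensity
  across all conditions.
- **Pathway importance.** score(pathway, condition) = produced
  metabolites in the pathway / distinct produced pathway-mapped
  metabolites in that condition.
- **PCA.** Conditions × metabolites, mean-centered (no scaling), full
  SVD, deterministic sign convention; the top-5 positive/negative
  loadings of a separating component identify signature exudates.

## Worked example

```python
import exoscreen as xs
from exoscreen import annotation as ann, exometabolome as exo, growth as gr, multivariate as mv

cfg = xs.paper_like_config(seed=42, noise_cv=0.05, n_ions=1000)
design, truth, curves, masses, features = xs.generate_screen(cfg)

effects = gr.classify_growth(gr.summarize_growth(curves), design.control_id)
print(effects["effect_class"].value_counts().to_dict())
# {'none': 22, 'inhibited': 21, 'complete_inhibition': 15, 'enhanced': 6}

annotations = ann.annotate_ions(features.ions, masses, tol_ppm=10)
met_ion = ann.metabolite_ion_map(annotations, features.intensities)
norm = exo.normalize(features, met_ion, exo.compute_lod(features, met_ion), design)

calls = exo.consumption(features, met_ion, design, threshold=0.10)
print(len(exo.mixotrophic_metabolites(calls)))   # 15

print(exo.rank_exudates(norm).head(3).to_string(index=False))
#            metabolite_id  summed_normalized_intensity  n_producing_conditions  rank
#              glutathione                    17.142680                      37     1
#         dihydroneopterin                    16.421639                      51     2
# hydroxy-formylkynurenine                    15.439473                      34     3

dead = set(effects.loc[effects.effect_class == "complete_inhibition", "condition_id"])
res = mv.pca(norm, n_components=5, exclude_conditions=dead)
pos, neg = mv.top_loadings(res, "PC2", k=5)
print(list(pos.index))
# ['hydroxyglutarate', 'glutarate', 'leucine', 'isopropylmalate', 'ketovaline']
print(list(neg.index))
# ['2-phosphoglycolate', 'formylglutathione', 'gluconate', '5-methyltetrahydrofolate', 'itaconate']
```

The screen plants 7 growth enhancers, 36 inhibitors (15 of them lethal),
15 consumed substrates and two condition-specific exudation signatures.
At 5% measurement noise with n = 3 the pipeline recovers 6 of 7
enhancers (the 1.10–1.12-fold effects are at the edge of detectability),
all 15 consumed substrates, and the two planted signatures: PC2
separates the valine-like response (positive loadings: branched-chain
intermediates) from the glucose-like response (negative loadings:
gluconate, 2-phosphoglycolate, itaconate, ...).

The same analysis runs from the shell:

```
exoscreen simulate --out data --seed 42
exoscreen validate data
exoscreen run-all --config config.yaml
```

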