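# mimiscape

Tools for estimating the **fitness landscape associated with polymorphic
Müllerian mimicry** from artificial-prey predation experiments and wing
colour-pattern images.

In a Müllerian mimic such as the butterfly *Heliconius numata*, several
discrete wing-pattern morphs coexist within a population, each protected by
local predator learning; each morph sits on a fitness *peak*. Heterozygotes
at the colour-pattern supergene can express intermediate, non-mimetic
phenotypes that predators fail to recognise — candidate fitness *valleys* —
unless they resemble a local morph closely enough to be generalised over, in
which case low-predation *ridges* connect nearby peaks. `mimiscape`
implements the full analysis chain needed to map that landscape:

1. **Colour Pattern Modelling (CPM)** — every wing pixel is categorised into
   one of four colour classes (black, orange, yellow, white), wings are
   aligned to an iteratively estimated average template by a similarity
   transform maximising class agreement, and each pattern is encoded
   per pixel. Phenotypic distance between two morphs is the Euclidean
   distance between their scores on the first eight components of a PCA of
   these encodings ("binary PCA": one-hot presence/absence per colour).
2. **Receptor-noise-limited vision models** — quantum catches
   Q_i = ∫ R(λ) I(λ) S_i(λ) dλ per photoreceptor class, channel noise
   e_i = ω·√(η_max/η_i) from a Weber fraction ω = 0.05 and cone abundance
   ratios η_i, and chromatic contrasts ΔS in just-noticeable-difference
   (JND) units. Observer presets: blue tit (UV-type vision, 300–700 nm,
   η = 1 : 1.92 : 2.68 : 2.70), peafowl (V-type, 400–700 nm,
   η = 1 : 1.9 : 2.2 : 2.1) and human (η = 1 : 16 : 32). Replacing the
   one-hot pixel values with each pixel class's quantum catches gives the
   perceptual "QC PCA", which weighs a pattern change by how conspicuous
   the colour change is to the chosen predator.
3. **Predation statistics** — for a table of placed dummies (five roles per
   station: dominant and recessive local homozygote, heterozygote, exotic
   morph, palatable control): χ² homogeneity of the palatable control's
   attack rate across sites; binomial GLMs (logit link) of attack by
   phenotype with closed-form pairwise log-odds contrasts and
   analysis-of-deviance; heterozygote/homozygote attack ratios regressed on
   phenotypic distance; and AIC comparison of nested GLMs in the two peak
   distances (het-homD, het-homR) and their interaction.
4. **Landscape assembly** — attack rates joined to phenotype-space
   coordinates; local morphs significantly less attacked than the exotic
   baseline are annotated peaks, heterozygotes that fail that test valleys,
   and ridge scores are attack-ratio slopes along the segment joining two
   peaks.
5. **Synthetic data** — parametric wing morphs (elliptical patches in
   wing-fraction coordinates, heterozygotes as geometric dominance blends
   with coefficient d), smooth reflectance spectra per colour class, and
   Bernoulli predation outcomes with role-dependent rates, so the entire
   pipeline runs and is testable with no external data.

## Worked example

```python
from mimiscape import (ExperimentDesign, simulate_predation,
                       fit_attack_glm, observer_preset, receptor_noise,
                       summarize_attacks)

design = ExperimentDesign(
    sites={f"site{i+1}": "groupA" for i in range(4)},
    groups_per_site=200, seed=42)          # 4 sites x 200 stations x 5 roles
table = simulate_predation(design)
print(summarize_attacks(table).per_role[["role", "n_recovered",
                                         "n_attacked", "rate"]])

glm = fit_attack_glm(table, reference_role="exotic")
c = glm.contrasts.query("role_a == 'exotic' and role_b == 'hom1'").iloc[0]
print(f"exotic vs hom1 log-odds: {c['estimate']:.3f} (se {c['se']:.3f}, "
      f"z = {c['z']:.2f}, p = {c['p']:.4f})")

obs = observer_preset("blue_tit")
print(dict(zip(obs.receptor_names, receptor_noise(obs).round(4))))
```

prints (seed 42):

```
     role  n_recovered  n_attacked   rate
   exotic          790          58 0.0734
      het          786          62 0.0789
     hom1          788          30 0.0381
     hom2          784          33 0.0421
palatable          785          35 0.0446
exotic vs hom1 log-odds: 0.694 (se 0.231, z = 3.01, p = 0.0026)
{'UVS': 0.0822, 'SWS': 0.0593, 'MWS': 0.0502, 'LWS': 0.05}
```

The unfamiliar exotic morph is attacked roughly twice as often as the local
homozygote (odds ratio e^0.694 ≈ 2.0, significant), the intermediate
heterozygote is attacked like the exotic — a fitness valley — and the
blue tit's rarest (UV) cone channel is the noisiest, as the receptor-noise
model prescribes.

The full pipeline (rendering, alignment, both encodings, three observers,
simulation, all statistics, landscape annotation) runs from one config:

```python
from mimiscape import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(seed=1, output_dir="out"))
print(bundle["landscape"].peaks, bundle["landscape"].valleys)
```

or from the shell: `mimiscape run --seed 1 --out-dir out` (see also
`mimiscape simulate`, `mimiscape vision`, `mimiscape stats`). Outputs are
tidy CSVs, `landscape.json` and diagnostic plots, byte-reproducible under a
fixed seed.

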