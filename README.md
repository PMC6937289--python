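# lodgekit

Culm biomechanics, split-plot field-trial statistics and two-color
microarray analysis for rice lodging-resistance studies.

Lodging — the permanent bending or breaking of the stem at its lower
internodes — is a major yield risk in intensively fertilized rice,
especially in typhoon-prone coastal regions. Agronomists evaluate lodging
resistance by treating each elongated internode as a hollow cylinder and
combining caliper geometry with a portable three-point bending tester;
gene-expression profiling of the lower internodes then connects the
mechanical changes to cell-wall and starch biology. `lodgekit` implements
that full analysis as a reusable, testable pipeline:

- **`lodgekit.biomech`** — per-internode mechanics. For outer radius *a* and
  wall thickness *t* (mm), the section moment of area is
  `I = π a⁴/4 · [1 − (1 − t/a)⁴] = π/4 · (a⁴ − (a−t)⁴)`; the elastic
  modulus from a mid-span deflection δ under load *F* over span *L* is
  `E = F L³ / (48 δ I)`; bending stiffness is the flexural rigidity `E·I`;
  the self-load bending moment is lever arm × fresh weight above the
  internode base; the lodging index is bending moment / breaking
  resistance; culm volume is the shell `π L (2at − t²)`; plumpness is dry
  weight per unit length and per unit volume.
- **`lodgekit.traits`** — group means ± standard errors over replicate-plot
  means, OPT-vs-FFP percent changes, split-plot ANOVA (nitrogen management
  on whole plots, variety on subplots, separate error strata) and Fisher's
  LSD letter groups at the 0.05 level.
- **`lodgekit.arraydx`** — two-color array pipeline: probe filtering, MA
  transform, robust loess normalization of M on A, per-probe one-sample
  t-tests across biological replicates, DEG calling by the joint two-fold +
  p ≤ 0.05 criterion, hypergeometric GO enrichment with Benjamini–Hochberg
  adjustment, and qPCR concordance regression.
- **`lodgekit.synthgen`** — seeded generators for split-plot trials,
  Agilent-44k-like two-channel arrays with intensity-dependent dye bias and
  spiked truth tables, and annotated GO universes.
- **`lodgekit.io` / `lodgekit.cli`** — CSV/TSV readers and writers
  (including GenePix-style headers) and a `lodgekit` subcommand CLI.

## Worked example

```python
import lodgekit as lk

I = lk.section_moment_of_area(a=4.85 / 2, t=0.54)   # mm^4
EI = lk.flexural_rigidity(1.9, I)                   # 1e-3 N m^2
V = lk.culm_volume(16.9, 0.2425, 0.054)             # cm^3
print(f"I  = {I:.2f} mm^4")
print(f"EI = {EI:.1f} x 10^-3 N m^2")
print(f"V  = {V:.2f} cm^3")
print(f"%change total lower-internode length = {lk.percent_change(22.7, 28.4)}")
```

```
I  = 17.24 mm^4
EI = 32.8 x 10^-3 N m^2
V  = 1.24 cm^3
%change total lower-internode length = -20.1
```

The third lower internode of an inbred variety under farmers' fertilizer
practice (diameter 4.85 mm, wall 0.54 mm, length 16.9 cm, E = 1.9 GPa) has
a section moment of 17.24 mm⁴, a bending stiffness of 32.8 × 10⁻³ N·m² and
a shell volume of 1.24 cm³; optimized nitrogen management shortens the
three lower internodes by 20.1 % in total — shorter, thicker basal
internodes are the morphological signature of improved lodging resistance.

The transcriptomics arm, end to end on synthetic data:

```python
from lodgekit.synthgen import ArrayConfig, gen_two_color_arrays
from lodgekit.arraydx import run_pipeline

replicates, truth = gen_two_color_arrays(ArrayConfig(), seed=42)
stats = run_pipeline(replicates)
print("up:", (stats['call'] == 'up').sum(),
      "down:", (stats['call'] == 'down').sum())
```

```
up: 665 down: 713
```

Three replicate 45,018-feature arrays with 665 up- and 713 down-regulated
probes planted at |log2FC| ~ U(1.5, 3) under a sinusoidal dye bias are
fully recovered after loess normalization.

The same steps are available from the shell:

```sh
lodgekit simulate-trial --seed 1 --out records.csv
lodgekit mech --in records.csv --out profiles.csv
lodgekit anova --in records.csv --trait length_cm --internode 3 --out aov.csv
lodgekit report --in records.csv --trait length_cm
```

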