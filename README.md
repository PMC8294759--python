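# mdinet

Mass-difference-network metabolomics: a tested, reusable implementation of
the inference chain used to read genotype-dependent metabolic responses out
of untargeted direct-infusion FT-ICR mass spectrometry — from raw peak lists
to molecular-formula annotation, multilevel PLS-DA feature selection, and
compound-class / reaction-direction enrichment.

## Who this is for

Metabolomics researchers working with ultrahigh-resolution direct-infusion
MS (sub-ppm mass accuracy, no chromatography) who want an auditable,
scriptable version of the following analysis chain, plus a ground-truthed
synthetic-data generator that makes every stage verifiable by recovery of
known answers:

1. **Preprocessing** — S/N ≥ 4 and intensity ≥ 1.5×10⁶ peak filtering,
   removal of peaks whose mass defect no CHNOPS+Na formula can realise at
   z = 1, robust polynomial recalibration to sub-0.1-ppm residuals,
   cross-sample alignment in a 1-ppm window, ¹³C isotopologue elimination
   (spacing 1.0033548 Da, intensity correlation r ≥ 0.9 with the parent),
   ≥ 10% presence filtering, 0.9 × feature-minimum imputation, log₂
   transformation.
2. **MDiN annotation** — a mass-difference network (MDiN) connects features
   *xᵢ, xⱼ* by an edge for mass difference *B* when
   |(m(xⱼ) − m(xᵢ)) − Δm(B)| < 0.1 ppm, where Δm(B) = m(product) −
   m(substrate) of a known biochemical transformation. Molecular formulas
   propagate from confidently identified seed nodes along edges, screened by
   element-ratio / element-count / RDBE plausibility rules and consistency
   with all annotated neighbours; nodes failing more than 10 assignment
   attempts are discarded.
3. **Feature selection** — two-class PLS-DA on log₂ intensities (or, for
   paired three-timepoint designs, on within-subject response matrices
   t₁−t₀ and t₂−t₁, the multilevel reduction), with sevenfold stratified
   cross-validation. Model quality is R² and Q² = 1 − PRESS/TSS; the
   iterative loop halves the feature set by |regression coefficient| until
   neither R² nor Q² improves.
4. **Enrichment** — sign-aware hypergeometric over-representation analysis
   (ORA) of compound classes in the selected subset, and mass-difference
   enrichment analysis (MDEA): for each transformation type, the edge subset
   with down-regulated substrate and up-regulated product ("forward") is
   tested for class enrichment of its source and target nodes — a
   direction-resolved, anabolic/catabolic readout.

## Worked example

Simulate a two-genotype, three-timepoint oral-glucose-tolerance-test (OGTT)
study in which 80% of steroid-class compounds rise 0.8 log₂ units at t₁ in
risk-genotype subjects only (so the immediate response t₁−t₀ goes up and the
short-term response t₂−t₁ comes back down), then run the full pipeline:

```python
from mdinet.config import PipelineConfig
from mdinet.pipelines import run_ogtt_pipeline
from mdinet.synthetic_data import (EffectSpec, make_compound_library,
                                   ogtt_design, simulate_study, write_dataset)

library = make_compound_library(n_per_class=30, seed=11)
design = ogtt_design(n_per_group=20, seed=11)
effects = [EffectSpec("Steroids and steroid derivatives", {"t1": 0.8}, fraction=0.8)]
peaklists, metadata, truth = simulate_study(library, design, effects)
write_dataset("demo/data", peaklists, metadata, truth)

res = run_ogtt_pipeline(PipelineConfig(seed=11), "demo/data", "demo/results", truth=truth)
```

Output of the summary printout:

```
features x samples: 186 x 120
network: 186 nodes, 75 edges, 164 annotated
immediate: final model 46 features, Q2=0.94; steroids up p=1.60e-12 (k=18/n=30), down p=1.00e+00 (k=0/n=16)
short_term: final model 46 features, Q2=0.93; steroids up p=9.61e-01 (k=1/n=22), down p=2.27e-10 (k=15/n=24)
```

Reading this: 210 simulated compounds (plus isotopologue and [M+Na]⁺
satellites) align into 186 features across 120 samples after cleaning; the
multilevel PLS-DA compresses each response into a 46-feature final model
with cross-validated Q² ≈ 0.93–0.94; and the ORA recovers the injected
pattern — the steroid class is significantly **up** in the immediate
response (18 of the 30 positively-signed selected features are steroids,
p = 1.6×10⁻¹², hypergeometric upper tail) and significantly **down** in the
short-term response (p = 2.3×10⁻¹⁰), with the opposite directions null.
`demo/results/` holds every intermediate as TSV (feature matrix, network
edge list and GraphML, annotations, selection traces, ORA/MDEA tables,
tile-map statistics).

The same stages are available as subcommands of the `mdinet` CLI
(`simulate`, `preprocess`, `network`, `select`, `enrich`, `mdea`,
`replicate`, `run-mouse`, `run-ogtt`), all driven by a YAML config whose
defaults are the study's printed operating points.

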