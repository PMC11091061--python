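# mycostats

Quantitative analysis of arbuscular-mycorrhizal-fungus (AMF) colonization
in plant roots, from instance-segmentation output to hierarchical
variance partitioning.

Most vascular plants trade photosynthetic carbon for soil nitrogen and
phosphorus through AMF colonizing their roots. Instance segmentation of
stained root micrographs yields, per image, the fungal structures present
— arbuscules (arb), extraradical and intraradical hyphae (exH, inH),
vesicles (ves), spores (sp) — each with a pixel area and a classifier
confidence. `mycostats` turns those records into slide-level colonization
phenotypes and asks the two questions such experiments are designed
around: *does colonization differ between root regions?* and *does the
allocation to fungal structures differ between plants?*

It is aimed at plant–microbe interaction labs running high-throughput
root phenotyping, and at anyone who needs two-level mixed models with
variance-partition diagnostics on nested (samples-within-individuals)
designs.

## What it computes

**Phenotypes per slide** (records below the confidence threshold, default
0.7, are discarded first): count density `n_c / root_px`, average
structure size `px_c / n_c`, percent colonization `px_c / root_px`,
totals over the five AMF classes, and the proportion of nutrient-exchange
structures `PNE = (n_arb + n_exH) / Σ n_AMF`.

**Mixed linear models.** Slides j nested in plants i:

    y_ij = β₀ + β₁·region_ij + β₂ᵀ x_ij + u_0i + u_1i·x_1ij + ε_ij
    (u_0i, u_1i) ~ N(0, Σ_u),   ε_ij ~ N(0, σ²_ε)

fitted by REML (ML for model comparison), with the diagnostics used to
read such model ladders:

- ICC = σ²_u0 / (σ²_u0 + σ²_ε), the between-plant share of variance;
- PCV = (v_ref − v_new) / v_ref, the proportional change of a variance
  component against the null model;
- VPC(x) = (σ²_u0 + σ²_u1 x² + 2σ_u01 x) / (σ²_u0 + σ²_u1 x² + 2σ_u01 x + σ²_ε),
  the ICC's quadratic generalization under a random slope;
- marginal / conditional R², AIC, BIC, deviance, likelihood-ratio tests.

**Workflow**: Lasso screening (seeded CV, 1-SE rule) → forward selection
by LRT → random-slope selection by LRT → the null-to-full model ladder →
Tukey region contrasts → Spearman rank comparison of phenotypes.

**Annotation geometry**: VGG Image Annotator JSON/CSV parsing, 512-pixel
tiling with clipped sub-polygons, even-odd repair of self-intersecting
rings, pixel-center rasterization.

**Segmentation evaluation**: mask IoU, greedy class-wise matching,
101-point AP / AP50 / mAP over IoU 0.50:0.05:0.95, confidence-score
summaries, Fisher's exact test (2×K, enumeration or Monte Carlo) for
class-frequency agreement.

**Synthetic data**: seeded generators for design tables drawn from the
mixed model, correlated per-slide instance tables (Gaussian copula over
Poisson counts, plant- and region-level effects), and truth/prediction
mask pairs with independent matching bookkeeping — so the entire pipeline
runs and is testable without any image download.

## Worked example

```python
import mycostats as m

# a synthetic study: 12 plants x 3 root regions x 3 replicates
design, truth = m.simulate_mlm_dataset(m.SimParams(seed=11))
records = m.simulate_instance_tables(m.InstanceSimParams(seed=11), design)

phen = m.aggregate_slides(records, conf_threshold=0.7)
res = m.run_colonization_analysis(
    records, design[["slide_id", "plant", "region", "replicate"]], seed=11
)
```

which prints, via the fields of `res`:

```
10332 instance records on 108 slides
mean percent colonization: 0.290
mean PNE:                  0.666
null-model ICC (plant-level share): 0.562
final model: model_10_slope_count_arb_scaled
  PCV plants 1.000 | PCV samples 0.882
  conditional R2 0.946 | AIC -409.9
PNE ICC: 0.629
Spearman rho (pct colonization vs PNE across plants): 0.385
```

Reading: before any predictor is added, 56% of the variance in percent
colonization sits between plants (the null ICC). Adding root region and
the selected structure covariates absorbs essentially all of that
plant-level variance (PCV plants ≈ 1.0) and 88% of the within-plant
sample variance — differences in colonization between these synthetic
plants are carried by their fungal-structure composition, which is
exactly the mechanism the generator builds in. The final model keeps a
random slope on scaled arbuscule count, so the plant-level share is
reported as a VPC. PNE clusters at the plant level too (ICC 0.63), and
plants rank broadly similarly under percent colonization and PNE
(ρ = 0.39).

The same stages are scriptable from the shell:

```sh
mycostats simulate --preset model6 --seed 11 --outdir demo/
mycostats phenotypes demo/instances.tsv --out demo/phenotypes.tsv
mycostats analyze demo/instances.tsv demo/design.tsv --seed 11 --outdir demo/out/
mycostats tile annotations.json --out tiled.json --tile-size 512
```

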