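# columnmorph

Quantifying serial disparity, evolutionary constraint and ecomorphological
signal along metameric skeletal systems — built around the mammalian
presacral vertebral column (C03–C07 plus a thoracolumbar series whose total
count is fixed at 20 while the thoracic/lumbar boundary shifts between
species).

The package is aimed at geometric morphometricians and comparative
biologists who have per-vertebra 3D landmark data across many species, a
time-calibrated phylogeny, and ecological classifications, and who want to
ask: *which column segments are morphologically disparate, which are
evolutionarily constrained, and where does locomotor ecology leave its
imprint?*

## What it computes

For landmark configurations **X**ᵢ (K × 3 per vertebra):

- **Symmetric-shape alignment.** Generalized Procrustes analysis with
  object symmetry: each configuration is superimposed jointly with its
  relabelled mirror image and the per-specimen mean of the two aligned
  copies is kept, removing digitisation asymmetry. Species represented by
  several specimens are averaged.
- **Serial disparity.** Per-group Procrustes variance
  PV = (1/n) Σᵢ ‖xᵢ − x̄‖², standardised by the region's landmark count so
  regions with different K (34/32/36) are comparable. Groups come from two
  seriation schemes: *by number* (all C03, all T14, …; positions beyond the
  shared minimum restricted to the species that have them) and *by
  position* (Tfirst, Tmid, Tdiaph, Tlast, Lfirst, Lmid, Llast, with the
  count-dependent rules for the intermediates).
- **Constraint (DTT/MDI).** Disparity-through-time curves of relative
  subclade disparity (average squared pairwise distance convention) on
  allometry-corrected shape data, against a multivariate Brownian-motion
  null with rates estimated by phylogenetic independent contrasts. The
  morphological disparity index is MDI = ∫₀¹ (DTT_obs − DTT_BM) dt; high
  positive values mean subclades keep overlapping in morphospace, i.e.
  constrained evolution.
- **Ecomorphology.** Species are coded for five binary locomotor
  capabilities (terrestrial, cursorial, arboreal, aquatic, fossorial).
  Phylogenetic Procrustes ANOVA (generalized least squares through the
  inverse square root of the Brownian covariance) with residual-
  randomization permutation (RRPP) tests shape ~ capability associations;
  an exhaustive search over all capability subsets keeps the model with
  the highest R² among those whose terms are all at least marginally
  significant (p < 0.1).
- **Serial comparisons.** Within-region Procrustes ANOVAs with vertebral
  position as factor, and AR1-GLS regressions among the per-position
  metric series (disparity ~ MDI, disparity ~ R², MDI ~ R²) that account
  for the serial correlation of adjacent vertebrae.

A first-class synthetic-data generator (`columnmorph.synthetic`) emulates
the whole study design — pure-birth tree, homeotic count variation,
bilaterally symmetric landmark templates, region-specific OU/BM regimes,
capability effects — with recorded ground truth, so every estimator is
testable end to end without the original CT data.

## Worked example

```python
import columnmorph as cm

config = cm.RunConfig(
    out_dir="out", seed=7, scenario="paper_like", n_species=16,
    n_perm=199, n_sim=50, min_group_species=6,
)
results = cm.run_full_analysis(config)

print(results["mdi"]["by_number"].groupby("region")["mdi"].mean())
fit = results["serial_gls"]["by_number"]["disparity_vs_mdi"]
print(f"disparity ~ MDI: slope={fit.slope:.2e} p={fit.slope_p:.3f} phi={fit.phi:.2f}")
```

prints (seed 7):

```
region
cervical    0.362141
lumbar      0.247438
thoracic    0.300749
Name: mdi, dtype: float64
disparity ~ MDI: slope=-1.31e-04 p=0.060 phi=0.85
```

Cervical vertebrae show the highest MDI (strongest constraint — subclades
keep re-exploring the same morphospace), lumbars the lowest; and the
negative slope says that along the column, positions with high
among-species disparity are those with weak constraint (at this reduced
16-species/26-position size the slope is marginal; at the full 44-species
scale of `scripts/acceptance.py` it is clearly significant, p ≈ 0.003). The same run
writes `disparity_*.csv`, `mdi_*.csv`, `ecology_*.csv`, `position_anova.csv`,
`serial_gls.csv` and a provenance manifest into `out/`.

The same workflow runs from files (landmark `*.txt` directory, metadata
CSV with counts and the diaphragmatic position, Newick tree, capability
CSV) via `RunConfig(landmarks_dir=..., metadata_path=..., tree_path=...,
capabilities_path=...)`, or from the shell:

```sh
columnmorph simulate --scenario paper_like --n-species 44 --seed 1 --out data/
columnmorph run-all --scenario paper_like --n-species 44 --seed 1 --out out/
```

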