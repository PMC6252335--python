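# faceherit

Spatially dense heritability and co-heritability of 3D facial shape in a
father–offspring design.

Classical craniofacial heritability studies reduce the face to a handful
of landmarks or preselected principal components and estimate a
heritability per measurement. `faceherit` instead works with spatially
dense, corresponded quasi-landmark configurations (hundreds to thousands
of homologous surface points per subject) and asks three questions at
once: how heritable is shape at every surface point, how strongly are
different facial locations *co*-inherited, and how heritable are
multivariate facial modules defined by that co-inheritance. It is aimed
at quantitative geneticists and morphometricians working with
parent–offspring imaging cohorts; because such cohorts are usually
access-controlled, the package ships a synthetic family-shape simulator
with planted, known heritability structure so the full pipeline can be
exercised and validated end to end.

## Model and estimator

For paired configurations the pipeline:

1. **Aligns and symmetrizes.** Generalized Procrustes analysis (GPA)
   removes position, orientation and size from originals and their
   relabeled mirror images combined; the symmetric component
   ½(aligned + aligned-reflection) is analyzed. Outlier faces are
   flagged by z-scored Procrustes distance to the consensus (z ≥ 2).
2. **Adjusts covariates.** Age, sex and BMI effects are removed per
   cohort by a full-rank PLSR (equivalently, multivariate OLS).
3. **Estimates h².** Offspring shape **Y** is regressed on father shape
   **X** by partial least squares regression (PLSR handles p ≫ n and
   collinearity). The multivariate shape coefficient of determination

   R² = 1 − Σᵢ d²(yᵢ, ŷᵢ) / Σᵢ d²(yᵢ, ȳ)

   is converted to a regression coefficient b = √(R² · SS_Y / SS_X)
   (the multivariate analogue of b = r·s_y/s_x), and in a one-parent
   one-offspring additive design **h² = 2b**.
4. **Maps co-heritability.** Applying the estimator to every (father
   landmark i, offspring landmark j) pair of 3D blocks yields a K×K
   matrix: the diagonal is the landmark heritability map, off-diagonal
   entries the pairwise co-heritability.
5. **Segments the face.** Five levels of recursive spectral bisection
   (normalized Laplacian, sweep-cut refined) of the symmetrized matrix
   give 63 nested modules of co-inheritance; alternative segmentations
   are compared by normalized mutual information (NMI).
6. **Scores modules.** Each module gets its own GPA + PCA shape space
   with the PC count chosen by Horn's parallel analysis; h² per module
   and cohort (sons / daughters) uses all retained PCs jointly, with
   permutation p-values (pairing randomized) and a Bonferroni threshold
   α = FWER / M_eff, where M_eff is the Li–Ji effective number of tests
   from the eigenvalues of the 63×63 matrix of pairwise RV coefficients
   between module score blocks.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
synthetic cohort of 762 father–offspring pairs with K = 242 landmarks
and four planted modules of true h² 0.8 / 0.6 / 0.4 / 0.2:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_preprocess.py
python 03_landmark_coheritability.py
python 04_segmentation.py
python 05_modular_heritability.py
python 06_stability_and_morphs.py
```

`02` reports QC: `retained 709 pairs (53 excluded by QC)` — pairs in
which either face sits ≥ 2 SD from the consensus are dropped, the same
z-score rule a real cohort needs for mapping errors and non-neutral
expressions.

`03` prints the landmark-level map averaged within each planted module:

```
mean landmark h2 per planted module (plant: 0.8 / 0.6 / 0.4 / 0.2):
  module 0: 0.711
  module 1: 0.615
  module 2: 0.360
  module 3: 0.227
```

The ordering of the plant is recovered; values are attenuated relative
to truth because a single landmark only partially projects onto the
module's latent factors, and weak modules ride on the estimator's
positive floor (h² = 2b is non-negative by construction).

`04` segments the matrix into 63 nested modules and compares each level
with the planted labels (`level 3: NMI vs planted modules = 0.829`).
`05` reports the modular estimates, e.g.

```
M_eff = 19.00 over 60 modules -> adjusted alpha = 0.00263
daughters: 47/60 modules significant, h2 range 0.00-0.85 (global face: 0.62)
sons:      50/60 modules significant, h2 range 0.00-0.84 (global face: 0.57)
```

i.e. the strong dependence between nested, spatially overlapping
modules reduces 120 tests to 19 effective ones, and the global-face
estimates sit near the planted average (≈ 0.5) for both cohorts. `06`
shows the h² stability curve: subsamples of 50–100 pairs are erratic
(SD 0.3–0.4), 400+ pairs give stable estimates (SD < 0.03).

The same pipeline runs from a config file via the CLI
(`faceherit run-all --config cfg.yaml`) and, for real data, from a
directory of per-subject `.xyz` configurations with a template mesh,
pairing and covariate tables (see `faceherit.io_shapes`).

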