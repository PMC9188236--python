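# Methods

This note documents the models, parameter choices and numerical conventions
behind `woodid`, and what the synthetic experiments do and do not show.

## LPQ descriptor

The descriptor follows the classical phase-quantization construction: at
each pixel the short-term Fourier transform over an M×M window is sampled
at u₁=(a,0), u₂=(0,a), u₃=(a,a), u₄=(a,−a); the 8-vector
g = [Re F₁..F₄, Im F₁..F₄] is sign-quantized, bit j = 1 iff gⱼ ≥ 0 (least
significant bit first), and the image is summarised by the normalised
256-bin histogram of codes.

Choices and conventions:

* **Window size M = 7, a = 1/M, no decorrelation, by default.** The window
  size trades locality against frequency resolution; 7 is the common
  default for texture work at these image scales. a = 1/M puts the samples
  exactly one DFT bin from DC, which makes Σ e^(−2πiad) vanish over the
  window and hence makes the descriptor exactly invariant to additive
  intensity offsets. All three are exposed in `LPQConfig` and recorded in
  outputs.
* **Valid-region coding.** Only pixels whose full window fits inside the
  image are coded; no padding, so histograms contain no border artefacts.
  An H×W image yields (H−M+1)×(W−M+1) codes.
* **Zero snapping.** Coefficients whose magnitude is below
  1e−9 · max(1, max|img|) · M² are treated as exact zeros before
  quantization. Analytically-zero coefficients (constant patches; the
  DC-offset contribution at a = 1/M) otherwise land on either side of zero
  depending on floating-point summation order. With the snap, a constant
  image deterministically codes to 255 everywhere and positive affine maps
  x → αx + β leave the code image unchanged. The brute-force test oracle
  applies the same convention.
* **Optional whitening.** When `decorrelate=True`, g is rotated by Vᵀ from
  the SVD of W Σ Wᵀ, where Σᵢⱼ = ρ^{‖xᵢ−xⱼ‖} (first-order Markov model,
  ρ = 0.9) over window positions and W is the real 8×M² STFT matrix. Off by
  default.

Correctness is established against an independent per-pixel double-loop DFT
oracle (exact code-image equality on random images for M ∈ {3, 5}).

## Preprocessing and augmentation

Colour images are converted with luma weights (0.299, 0.587, 0.114), then
histogram-stretched per image: intensities are clipped at the 1% and 99%
quantiles and rescaled to [0, 1] (constant images pass through). Stretching
happens on the full image, before partitioning.

Four regimes: original; halves (top/bottom, giving rows×columns =
H/2 × W); quadrants (row-major, H/2 × W/2); and OGRN, which partitions into
quadrants and keeps the first Original, Gaussian-smoothes the second
(σ = 1, truncated at 4σ, reflective borders), Rotates the third 90° CCW and
salts the fourth with impulse noise at density 0.05 — exactly
round(0.05·N) pixels chosen without replacement, half set to 0 and half to
1, the odd extra pixel dark. The split axis for halves, the rotation
direction, and the 50/50 salt/pepper share are conventions fixed here for
reproducibility; they do not affect histogram statistics materially.
Augmentation never touches labels, tree ids or views.

## Forests and multi-view stacking

Per-view forests use 500 trees with 15 candidate features per split
(`mtry`), bootstrap sampling of size n. Bootstrap membership is retained:
the vote profile of a *training* specimen is computed from its out-of-bag
trees only (≈ T/e ≈ 184 of 500), while *test* profiles use all trees. If a
training observation were in-bag for every tree (probability ≈ (1−e⁻¹)ᵀ,
negligible at T = 500) the uniform profile is defined as the fallback; a
guard asserts the OOB tree set is never empty in practice.

The meta-learner is a multinomial logistic regression on the concatenated
3q-dimensional OOB profiles, with an L2 penalty of strength 1.0: stacked
meta-features are often linearly separable and the unpenalised maximum
likelihood estimate would diverge. Ties in the final argmax are broken by
class-list order. The feature-concatenation baselines (two or three views,
512- or 768-dimensional) train a single forest on the concatenated
histograms.

Specimen pieces are linked across views positionally by
(specimen, piece index): piece 2 of the transverse image pairs with piece 2
of the tangential and radial images — the only deterministic pairing
available.

## Hierarchical costs

C(y,y′) = 0 / 1 / 1.25 / 1.5 by taxonomic distance (configurable but
ordered). The Bayes decision minimises posterior expected cost; with the
flat 0/1 cost it provably reduces to the posterior argmax, which is checked
against exhaustive risk minimisation for random posteriors. H-Loss is the
mean pairwise cost; its supremum under the default levels, 1.5, is attained
exactly when every prediction crosses families.

The bundled 77-species taxonomy reproduces the reference collection's
printed totals (77 species, 58 genera, 25 families) when the Fabaceae
subfamily qualifiers are kept as family-level labels (Detarioideae,
Caesalpinioideae, Papilionoideae), the "Mimosoid clade" qualifier is folded
into Caesalpinioideae, and the Malvaceae/Moraceae subfamily qualifiers are
dropped; genus is the first epithet of the binomial.

## Cross-validation protocols

* **Naive stratified k-fold (default k = 4).** The assignment unit is the
  specimen-piece group (all three views together), stratified by species
  with per-species fold sizes differing by at most one. Pieces of one tree
  may split across folds — deliberately, since that leak is the object of
  study.
* **Leave-k-trees-out.** Per species, one randomly chosen tree's records
  form the test set; species with a single tree go wholly to training and
  are reported as untestable. The split is repeated over derived seeds
  (default 5 repeats) to obtain a spread, as a single split has high
  variance.

Reports carry accuracies at species/genus/family level (monotone by
construction: a species match implies a genus match implies a family
match), H-Loss, per-species accuracy, fold-wise accuracy mean ± sd, and a
confusion matrix ordered by family, then genus, then species.

## Synthetic data generator

Each (species, view) owns an oriented sinusoidal grating (orientation θ,
frequency f in cycles/pixel) mixed with a deterministic band-pass noise
texture (difference of Gaussian blurs of white noise, σ 1.2 and 3.5) at
weight w ∈ [0.15, 0.30]. Species sharing grating parameters share the
texture, so the texture cannot leak identity where a view is meant to be
uninformative. Genus base orientations are spread uniformly over [0, π)
per view; congeners sit within ±5° of their genus base and within ±3% in
frequency, emulating intra-genus confusability. Per (tree, view), δθ and
relative δf are drawn once from Normal(0, σ_tree²); per image, iid pixel
noise of sd σ_image is added and the result clipped to [0, 1].

Presets (all 4 trees/species × 4 images/tree, image size 128):

* **complementary** — 10 species; species index is decomposed into three
  base-3 digits and view v's orientation depends only on digit v, so no
  view identifies a species alone; σ_tree = 0.02, σ_image = 0.06.
* **tree-effect** — 8 species (2 families × 2 genera × 2); σ_tree = 0.25
  rad (≈ 14°, larger than the within-genus spacing), σ_image = 0.05.
* **null** — same structure with σ_tree = 0; σ_image = 0.35, chosen large
  so the task is not a trivial ceiling (the LPQ histogram, averaging
  thousands of codes, is extremely robust to iid pixel noise, so accuracy
  remains ≈ 0.99).

The default image size (128, not the 1000 px of real micrographs) and the
modest dataset sizes were chosen so the full multi-seed test suite runs at
desk scale; both are configuration, not constants.

What passing these tests shows: the pipeline's relative behaviours — the
multi-view gain under complementary views, the optimism of naive CV under a
tree-level variance component, the monotone accuracy hierarchy — and the
exactness of the descriptor and decision rules. What it does not show:
absolute accuracy on real wood anatomy, which depends on vessel/ray/
parenchyma structure, staining and slide preparation variability that the
grating model makes no attempt to imitate.

## Known limitations

* The LPQ window size and decorrelation setting used for the published
  real-data accuracies are not recorded anywhere; results on real imagery
  will depend on them. Both are exposed in `LPQConfig`.
* The meta-learner assumes every training specimen has all three views;
  specimens with missing views are rejected, not imputed.
* The grouped protocol holds out whole trees but not, e.g., collection
  sites or time periods; broader grouping would need extra metadata.
* Model files written by `woodid train` use joblib serialisation and are
  not portable across major scikit-learn versions.
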