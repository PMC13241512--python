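# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `spectromatch`. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## Spectrum representations

Each modality is mapped onto a fixed grid before encoding. Axes are stored
in increasing physical units; the NMR convention of plotting chemical shift
decreasing to the right is treated as presentation only, which avoids
double-reversal bugs.

| modality | representation | axis | length |
|---|---|---|---|
| ¹³C NMR | binary presence vector | 0–300 ppm | 512 bins (≈ 0.59 ppm/bin) |
| ¹H NMR | intensity vector, min-max scaled to [0, 1] | −2 to 10 ppm | 10,000 |
| IR | transmittance vector, min-max scaled to [0, 1] | 600–3800 cm⁻¹ | 1600 (2 cm⁻¹/element) |
| HSQC | 2-D grid, max-normalised | ¹³C 0–300 ppm × ¹H −2–10 ppm | 512 × 512 |

Details and edge rules:

- ¹³C shifts are floored into bins of width 300/512 ppm; a shift exactly at
  300 ppm clamps into the last bin. Out-of-range peaks are dropped with a
  logged warning rather than wrapped — silent wrap-around would corrupt
  training pairs. The 512-bin length is configurable.
- ¹H peak lists are rendered as sums of Lorentzian lines (the natural NMR
  line shape; a Gaussian alternative is configurable) before sampling onto
  the 10,000-point grid. A constant trace min-max-scales to all zeros (the
  degenerate-scale rule), logged.
- IR regions with no measurement are filled with transmittance 1.0 — the
  physically neutral "no absorption" baseline. Peak-list input is treated
  as Gaussian absorption bands subtracted from that baseline.
- HSQC peaks are reconstructed from (centroid, min, max) on both axes as
  2-D Gaussians with per-axis σ = (max − min)/4, floored at one grid cell;
  the min/max extent then sits at roughly ±2σ. Peaks entirely outside the
  window are dropped and logged.
- `resample_linear` reduces long instrument traces (e.g. 32,768 points) to
  the model grid by linear interpolation with exact endpoint preservation.
  It commutes with affine transforms of the values, which the property
  tests exercise.

Augmentations emulate measurement variability: peak-position jitter
(default σ = 0.01 ppm), width broadening (×1.1), additive noise (1% of the
maximum) and a slow sinusoidal baseline drift (2%). The exact published
augmentation suite is not public; these defaults are the package's own,
they are all surfaced in `AugmentationConfig`, and identical seed + config
always reproduces the same augmented spectrum. A Monte-Carlo test confirms
the jitter's empirical standard deviation matches its configured scale.

## Synthetic chemistry

`generate_corpus` grows random small organic molecules (default palette
C, H, O, N, Cl; 3–15 heavy atoms; at most 5 each of O, N, Cl) by seeded
graph growth with occasional double bonds, aliphatic ring closures and
aromatic-ring seeds. Structures are sanitised and canonicalised with RDKit
and deduplicated; infeasible requests fail explicitly.

`simulate_spectra` assigns peaks from fixed environment tables: one ¹³C
peak per symmetry-distinct carbon (canonical atom ranking), with base
shifts by environment class (carbonyl ≈ 170–200, aromatic ≈ 128, C–O ≈ 62,
alkyl ≈ 12–36 ppm) plus a deterministic ±6 ppm offset hashed from the
radius-2 atom environment; one ¹H multiplet per hydrogen-bearing
environment with intensity proportional to the hydrogen count; IR bands
per functional group present plus three hashed fingerprint-region bands;
one HSQC peak per C–H environment pair. Simulation is a pure function of
(structure, seed, config).

These tables are synthetic. Their only contract is *consistency* (the same
structure always yields the same spectra) and *discriminability* (a test
asserts ≥ 95% of molecules in a 300-molecule corpus have pairwise-distinct
binary ¹³C vectors). They do not reproduce real chemical shifts, coupling
patterns, solvent effects or instrument artefacts. Consequently, passing
tests demonstrate that the alignment-retrieval-refinement *mechanism* works
when spectra are informative about structure — not that the trained toy
encoders transfer to real instrument output.

## Encoders and contrastive alignment

All encoders project into a shared d = 64 space (configurable) through a
linear head followed by L2 normalisation, so every similarity in the system
— the training loss, retrieval fusion and the GA reward — is a cosine. At
desk scale the architectures are deliberately small:

- ¹³C: MLP 512 → 256 → 256 → 64.
- ¹H and IR: fixed average-pooling front end (10,000 → 250; 1600 → 200),
  then the same MLP shape.
- HSQC: 16× 2-D average pooling (512² → 32²), flatten, MLP.
- Molecule: SMILES token + learned position embeddings (token dim 32), one
  single-head self-attention block with a residual connection, a per-token
  feed-forward layer, masked mean pooling, linear head. The per-token
  nonlinearity is applied *before* pooling deliberately: with pooling
  first, the embedding is nearly invariant to token rearrangements, and
  formula-preserving "anagram" isomers become indistinguishable — exactly
  the candidates the GA produces under the formula penalty.

The published system uses far larger encoders (ResNet-style CNNs with
self-attention for ¹H/HSQC, a CNN for IR, a pretrained transformer for
SMILES) trained on ~794k pairs; the architectures here keep the same
modality-to-encoder-family mapping where it is cheap (¹³C MLP, molecule
transformer) and replace convolution stacks with pooling + MLP where it is
not. The learning dynamics being tested — symmetric InfoNCE alignment with
a molecule-embedding hub — are unchanged. The networks run on a compact
reverse-mode autodiff engine (`spectromatch.autodiff`, float64 NumPy)
whose gradients are verified against central differences in the tests.

Training follows the standard recipe: symmetric InfoNCE at temperature
τ = 0.07, Adam at learning rate 1e-4, early stopping with patience 3
epochs, best-validation checkpoint returned, batch size 16 by default.
Each spectral modality is aligned against the molecule embedding (hub
design) and the per-batch loss sums over available modalities; summing
rather than alternating modalities between steps was chosen for
determinism and simplicity.

**Validation design.** By default `fit` holds out 10% of molecules and
monitors their loss. On a 300-molecule toy corpus this measure saturates
within ~10 epochs at the generalisation limit of the small from-scratch
molecule encoder, halting training long before the system is usable. The
package therefore also accepts explicit validation pairs
(`validation_data=`), and the study configuration validates on *fresh
augmentation draws of the training molecules*: this matches the
dereplication deployment (the grounding database is known; queries are new
noisy measurements of its molecules) and makes early stopping measure
robustness to measurement noise. Under this setting the 300-molecule,
two-modality system trains in ~200 epochs (≈ 2 minutes on one CPU core) to
top-1 self-retrieval ≥ 0.99.

## Retrieval

Candidates are pre-filtered by molecular formula (exact match by default —
the formula is routinely available from high-resolution MS; a summed
per-element tolerance is exposed for degraded settings, and an empty pool
falls back to the full index). The fused score is the arithmetic mean of
per-modality cosines over exactly the modalities present (1–4), so queries
with any subset of modalities are comparable. Rankings sort by fused score
descending with canonical-SMILES tie-breaking for run-to-run determinism.
Top-k accuracy is reported for k ∈ {1, 3, 5, 20}.

## Genetic-algorithm refinement

The GA operates directly on RDKit molecular graphs:

- **Crossover** cuts one random acyclic single bond in each parent and
  joins one fragment from each at the cut points.
- **Mutation** applies one random edit: element swap within the palette,
  atom addition, terminal-atom deletion, single↔double bond toggle, or
  small-substituent append (C, O, N, Cl, CO, C=O). Kekulisation before
  editing and sanitisation after guarantee only valid structures survive.

Selection is rank-proportional; elitism (default 5) carries the best
candidates unchanged, which makes the best reward provably non-decreasing
per generation (tested exactly). Defaults: population 100, offspring 200,
mutation rate 0.05, 15 generations, 3 seeds — generations and seed count
follow the published protocol, the rest are standard graph-GA-scale
settings, all configurable. The initial population is the top-N (default
100) of the retrieval ranking over the formula pool, padded with mutated
copies when the pool is small. Off-formula candidates are penalised by
W/T, never filtered, preserving exploratory recombination. Invalid
candidate structures receive a −∞ reward sentinel and are excluded.

Seeded runs are aggregated by unioning populations, deduplicating by
canonical SMILES keeping each structure's best reward, and sorting with
canonical tie-breaks; an aggregation oracle test checks this against a
brute-force union-sort. Provenance ("retrieved" vs "generated") is kept
per candidate, with the scored retrieval pool merged into the final
ranking so database hits are always reportable. Matches are declared by
Morgan fingerprint equality (radius 6, 2048 bits) with exact canonical
equality reported alongside as a collision guard.

The wrong-atom count W includes hydrogens (the formula is defined
hydrogen-complete, and T counts all atoms of the target, so W and T are on
the same scale).

## Calibration

Pipeline scores are min-max scaled over the evaluation set itself (with an
option to freeze the constants for deployment) and binned into 10
equal-width bins; per-bin empirical accuracy versus mean score forms the
confidence curve, exported as CSV and figure with a threshold → expected
accuracy lookup. The evaluation sweeps graded augmentation strength
(levels 0–8× the default scales) over ¹H-only queries, so scores and
correctness both degrade and the score-accuracy association is measurable;
the package asserts its direction (positive Spearman correlation), not a
magnitude.

## Problem sizes and reproducibility

The study configuration used by the tests and the acceptance script:
300-molecule corpus, c13 + h1 modalities, d = 64, batch 16, ≤ 250 epochs
(≈ 2 min CPU); GA planted-target recovery over 20 seeded runs of
population 50 / offspring 100 / 15 generations (≈ 20 s); end-to-end
regeneration over 8 small-molecule queries with population 40 / offspring
80 / 10 generations / 3 seeds and mutation rate 0.35 (≈ 20 s); calibration
over 60 queries × 5 noise levels. These sizes were chosen so the full
pipeline is convincingly exercised on a single CPU core in minutes; they
are the package's study conditions, not tuned quantities. Every stochastic
stage draws its seed from a global seed via stable MD5-based fan-out
(`derive_seed`), so reruns with the same configuration reproduce rankings
byte-for-byte.

## Known limitations

- The toy spectra carry no coupling constants, solvent or instrument
  effects; phasing, baseline correction and solvent-peak removal of real
  data are out of scope.
- Stereochemistry is not scored (SMILES stereodescriptors pass through the
  tokenizer but the reward cannot distinguish stereoisomers with identical
  constitution); mixtures are out of scope.
- Exact-structure regeneration by the GA degrades with molecule size: for
  truths ≤ 8 heavy atoms the embedding reward identifies the planted
  structure essentially uniquely, while for 10–15 heavy atoms near-tied
  isomers appear and recovery becomes partial. The acceptance script
  reports the measured regeneration rate rather than hiding it.
- The trained encoders generalise only weakly to molecules unseen in
  training at this corpus scale; the supported deployment is retrieval
  against a known grounding database plus local GA refinement.
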