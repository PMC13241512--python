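# spectromatch

**Retrieve-then-refine structure elucidation from multimodal spectra.**

Identifying the molecular structure behind a set of spectra (¹H NMR, ¹³C NMR,
IR, HSQC) is a daily bottleneck in synthetic and natural-product chemistry.
`spectromatch` implements a two-stage, desk-scale pipeline for this problem:

1. **Cross-modal retrieval.** A spectrum encoder per modality and a SMILES
   token encoder are aligned contrastively into one shared embedding space,
   so a measured spectrum can be searched *directly against a database of
   molecules* by cosine similarity — no reference spectra needed. Queries may
   use any combination of 1–4 modalities; per-modality cosines are fused by
   their arithmetic mean.
2. **Genetic-algorithm refinement.** When the database does not contain the
   analyte, a graph genetic algorithm evolves the retrieved population —
   editing atoms, bonds and substructures directly on the molecular graph —
   to maximise the spectrum/structure agreement in embedding space.

The package is self-contained: a synthetic-chemistry module generates
molecule corpora and rule-based toy spectra with the statistical structure
the pipeline assumes, so every stage is trainable and testable offline.

## Model

Encoders are aligned with the symmetric InfoNCE objective. For a batch of
paired spectrum embeddings **q** and molecule embeddings **k**,

```
L(S,M) = mean_i [ -log( exp(qᵢ·kᵢ/τ) / Σⱼ exp(qᵢ·kⱼ/τ) ) ],
L_symm = L(S,M) + L(M,S),          τ = 0.07
```

with each available spectral modality aligned against the molecule embedding
(hub design) and the per-batch loss summed over modalities. Embeddings are
L2-normalised, so dot products are cosine similarities throughout.

GA candidates are scored by the reward

```
R = (1/N) Σ_x d_cos(ε_x, ε_molecule)  −  W/T,       x ∈ {available modalities}, N ∈ [1,4]
```

where `W` is the number of wrong atoms in the candidate's molecular formula
relative to the target formula (hydrogens included) and `T` is the target's
total atom count. The penalty keeps off-formula candidates alive but
disadvantaged, so the search stays exploratory. Three seeded GA runs of
fifteen generations are aggregated by best-score deduplication; candidate
identity is checked with Morgan fingerprints (radius 6, 2048 bits).
Min-max-scaled pipeline scores are calibrated against empirical accuracy in
equal-width bins to give confidence estimates.

## Worked example

```python
from spectromatch import (generate_corpus, simulate_spectra, AugmentationConfig,
                          SpectrumMoleculeAligner, build_index, rank,
                          GraphGARefiner, run_end_to_end, is_match)

# 1. synthetic corpus + toy spectra (fresh augmentation draws per molecule)
records = generate_corpus(120, max_heavy_atoms=10, seed=42)
aug = AugmentationConfig()
spectra = [simulate_spectra(r, ("c13", "h1"), seed=i, augment=aug)
           for i, r in enumerate(records)]
val = [simulate_spectra(r, ("c13", "h1"), seed=10_000 + i, augment=aug)
       for i, r in enumerate(records)]
smiles = [r.smiles for r in records]

# 2. contrastive alignment (tau = 0.07, lr = 1e-4, early stopping patience 3)
aligner = SpectrumMoleculeAligner(modalities=("c13", "h1"), batch_size=16,
                                  max_epochs=150, random_state=0)
aligner.fit(spectra, smiles, validation_data=(val, smiles))

# 3. retrieval: query with a fresh noisy measurement of phenol
index = build_index(records, aligner)
truth = records[8]          # Oc1ccccc1
query = simulate_spectra(truth, ("c13", "h1"), seed=999, augment=aug)
result = rank(index, aligner.encode_spectra(query), true_smiles=truth.smiles)

# 4. de novo: remove the truth from the database, let the GA regenerate it
keep = [i for i in range(len(records)) if records[i].smiles != truth.smiles]
refiner = GraphGARefiner(population_size=40, offspring_size=80, generations=10,
                         n_seeds=3, mutation_rate=0.35)
ranking, report = run_end_to_end(aligner, index.subset(keep), query,
                                 truth.formula, refiner=refiner, top_n=30, seed=0)
```

Output:

```
trained 150 epochs, best validation loss 2.046
true molecule Oc1ccccc1 retrieved at rank 1, fused score 0.724
R = +0.724  W = 0  generated  Oc1ccccc1    match = True
R = +0.606  W = 1  generated  Oc1ccccc1O   match = False
R = +0.540  W = 1  generated  OOc1ccccc1   match = False
```

With phenol in the database the query retrieves it at rank 1 (fused cosine
0.724). With phenol removed, the GA regenerates exactly the same structure
from the remaining pool (`match = True` under the radius-6 fingerprint
criterion); the runners-up carry a one-atom formula penalty (`W = 1`).

A command-line surface wraps the same stages:

```bash
spectromatch simulate data/ --n 300 --seed 0
spectromatch train data/corpus.smi models/ckpt --modalities c13,h1
spectromatch elucidate models/ckpt data/corpus.smi runs/query1 \
    --from-molecule "Oc1ccccc1"
spectromatch benchmark models/ckpt data/corpus.smi report.json
spectromatch calibrate models/ckpt data/corpus.smi calib/
```

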