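"""Shared fixtures: synthetic corpora and trained toy alignment systems."""

from __future__ import annotations

import numpy as np
import pytest

from spectromatch.chem import generate_corpus, simulate_spectra
from spectromatch.codec import AugmentationConfig
from spectromatch.contrastive import SpectrumMoleculeAligner
from spectromatch.retrieval import build_index


@pytest.fixture(scope="session")
def small_corpus():
    """40 small molecules for fast unit tests."""
    return generate_corpus(40, max_heavy_atoms=10, seed=11)


@pytest.fixture(scope="session")
def tiny_trained(small_corpus):
    """A quickly trained c13-only aligner over 40 molecules (smoke-scale)."""
    recs = small_corpus
    aug = AugmentationConfig()
    spectra = [simulate_spectra(r, ("c13",), seed=i, augment=aug)
               for i, r in enumerate(recs)]
    val = [simulate_spectra(r, ("c13",), seed=50_000 + i, augment=aug)
           for i, r in enumerate(recs)]
    smiles = [r.smiles for r in recs]
    aligner = SpectrumMoleculeAligner(
        modalities=("c13",), batch_size=8, max_epochs=120, random_state=1
    ).fit(spectra, smiles, validation_data=(val, smiles))
    index = build_index(recs, aligner)
    return {"records": recs, "spectra": spectra, "aligner": aligner, "index": index}


@pytest.fixture(scope="session")
def trained_system():
    """The study-scale system: 300 molecules, c13 + h1 encoders, d = 64.

    Training monitors fresh-augmentation validation pairs (dereplication
    setting) with the standard recipe: tau 0.07, lr 1e-4, patience 3.
    """
    records = generate_corpus(300, max_heavy_atoms=15, seed=7)
    aug = AugmentationConfig()
    spectra = [simulate_spectra(r, ("c13", "h1"), seed=i, augment=aug)
               for i, r in enumerate(records)]
    val = [simulate_spectra(r, ("c13", "h1"), seed=100_000 + i, augment=aug)
           for i, r in enumerate(records)]
    smiles = [r.smiles for r in records]
    aligner = SpectrumMoleculeAligner(
        modalities=("c13", "h1"), batch_size=16, max_epochs=250, random_state=0
    ).fit(spectra, smiles, validation_data=(val, smiles))
    index = build_index(records, aligner)
    return {
        "records": records,
        "spectra": spectra,
        "aligner": aligner,
        "index": index,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
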