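"""Synthetic molecule corpora and rule-based toy spectra.

The generator produces small organic molecules (default palette C, O, N, Cl,
3–15 heavy atoms) by random graph growth, and assigns each one deterministic
peak lists per modality from fixed environment shift tables plus a hashed
per-environment offset. The tables are synthetic: their contract is
consistency and discriminability across molecules, not chemical-shift
accuracy. Simulation is a pure function of (structure, seed, config).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .codec import (
    AugmentationConfig,
    CodecConfig,
    HSQCPeak,
    PeakList1D,
    SpectrumVector,
    augment_h1,
    bin_c13,
    rasterize_hsqc,
    vectorize_h1,
    vectorize_ir,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "SpectrumSet",
    "generate_corpus",
    "molecular_formula",
    "formula_string",
    "simulate_peaklists",
    "simulate_spectra",
]

MODALITIES = ("c13", "h1", "ir", "hsqc")


@dataclass(frozen=True)
class MoleculeRecord:
    """A corpus molecule: canonical SMILES, formula, size, identifier."""

    smiles: str
    formula: dict[str, int]
    heavy_atoms: int
    mol_id: str

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str | None = None) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        canonical = Chem.MolToSmiles(mol)
        return cls(
            smiles=canonical,
            formula=molecular_formula(canonical),
            heavy_atoms=mol.GetNumHeavyAtoms(),
            mol_id=mol_id or canonical,
        )


@dataclass
class SpectrumSet:
    """The 1–4 modality vectors attached to one query molecule."""

    vectors: dict[str, SpectrumVector] = field(default_factory=dict)

    def __post_init__(self):
        if not (1 <= len(self.vectors) <= 4):
            raise ValueError("a SpectrumSet holds between 1 and 4 modalities")
        for mod in self.vectors:
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality {mod!r}")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(sorted(self.vectors))

    def __getitem__(self, modality: str) -> SpectrumVector:
        return self.vectors[modality]

    def subset(self, modalities) -> "SpectrumSet":
        return SpectrumSet({m: self.vectors[m] for m in modalities})


def molecular_formula(smiles_or_mol) -> dict[str, int]:
    """Element → count map of the hydrogen-complete structure."""
    mol = (
        smiles_or_mol
        if isinstance(smiles_or_mol, Chem.Mol)
        else Chem.MolFromSmiles(smiles_or_mol)
    )
    if mol is None:
        raise ValueError(f"invalid structure: {smiles_or_mol!r}")
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def formula_string(formula: dict[str, int]) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    parts = []
    for el in ["C", "H"] + sorted(k for k in formula if k not in ("C", "H")):
        n = formula.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "Cl": 1, "S": 2, "F": 1, "Br": 1}
_ELEMENT_LIMITS = {"O": 5, "N": 5, "Cl": 5, "S": 3, "F": 5, "Br": 3}


def _free_valence(mol: Chem.RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
    return _MAX_VALENCE.get(atom.GetSymbol(), 0) - used


def _grow_molecule(rng: np.random.Generator, palette: tuple[str, ...],
                   max_heavy: int) -> str | None:
    """Grow one random molecule by atom addition; returns canonical SMILES."""
    heavy_palette = [e for e in palette if e != "H"]
    weights = np.array([4.0 if e == "C" else 1.0 for e in heavy_palette])
    weights /= weights.sum()

    if "C" in heavy_palette and max_heavy >= 7 and rng.random() < 0.25:
        mol = Chem.RWMol(Chem.MolFromSmiles("c1ccccc1"))
    else:
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom("C" if "C" in heavy_palette else heavy_palette[0]))
    target = int(rng.integers(3, max_heavy + 1))

    while mol.GetNumAtoms() < target:
        sites = [i for i in range(mol.GetNumAtoms()) if _free_valence(mol, i) >= 1]
        if not sites:
            break
        anchor = int(rng.choice(sites))
        symbol = str(rng.choice(heavy_palette, p=weights))
        new_idx = mol.AddAtom(Chem.Atom(symbol))
        order = Chem.BondType.SINGLE
        # occasional C=O / C=C double bond where both ends allow it
        if (
            rng.random() < 0.15
            and _free_valence(mol, anchor) >= 2
            and _MAX_VALENCE[symbol] >= 2
        ):
            order = Chem.BondType.DOUBLE
        mol.AddBond(anchor, new_idx, order)
        # rare aliphatic ring closure
        if rng.random() < 0.05 and mol.GetNumAtoms() >= 5:
            cands = [
                i
                for i in range(mol.GetNumAtoms() - 1)
                if _free_valence(mol, i) >= 1
                and i != anchor
                and mol.GetBondBetweenAtoms(i, new_idx) is None
                and _free_valence(mol, new_idx) >= 1
            ]
            if cands:
                j = int(rng.choice(cands))
                if len(Chem.GetShortestPath(mol.GetMol(), j, new_idx)) >= 4:
                    mol.AddBond(j, new_idx, Chem.BondType.SINGLE)
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
    except Exception:
        return None
    return Chem.MolToSmiles(m)


def _within_limits(formula: dict[str, int], max_heavy: int, heavy: int) -> bool:
    if not (3 <= heavy <= max_heavy):
        return False
    for el, cap in _ELEMENT_LIMITS.items():
        if formula.get(el, 0) > cap:
            return False
    return True


def generate_corpus(
    n: int,
    max_heavy_atoms: int = 15,
    element_palette: tuple[str, ...] = ("C", "H", "O", "N", "Cl"),
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Generate `n` distinct valid molecules; deterministic given `seed`.

    Raises RuntimeError if the constraints make `n` unreachable within the
    attempt budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    attempts = 0
    budget = 400 * n + 1000
    while len(records) < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could only generate {len(records)}/{n} distinct molecules "
                f"within {budget} attempts; constraints may be infeasible"
            )
        smi = _grow_molecule(rng, element_palette, max_heavy_atoms)
        if smi is None or smi in seen:
            continue
        mol = Chem.MolFromSmiles(smi)
        formula = molecular_formula(mol)
        if not _within_limits(formula, max_heavy_atoms, mol.GetNumHeavyAtoms()):
            continue
        seen.add(smi)
        records.append(
            MoleculeRecord(smi, formula, mol.GetNumHeavyAtoms(), f"mol{len(records):05d}")
        )
    return records


# ---------------------------------------------------------------------------
# Toy spectrum simulation
# ---------------------------------------------------------------------------


def _hash_unit(key: str) -> float:
    """Deterministic pseudo-random float in [0, 1) from a string key."""
    digest = hashlib.md5(key.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def _atom_environment(mol: Chem.Mol, idx: int, radius: int = 2) -> str:
    env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, idx, useHs=False)
    if env:
        amap: dict[int, int] = {}
        frag = Chem.PathToSubmol(mol, env, atomMap=amap)
        root = amap.get(idx, 0)
        return Chem.MolToSmiles(frag, rootedAtAtom=root, canonical=True)
    atom = mol.GetAtomWithIdx(idx)
    return f"{atom.GetSymbol()}{atom.GetTotalNumHs()}"


def _symmetry_classes(mol: Chem.Mol) -> list[int]:
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False))


def _c13_base_shift(mol: Chem.Mol, idx: int) -> float:
    atom = mol.GetAtomWithIdx(idx)
    nbr_syms = [n.GetSymbol() for n in atom.GetNeighbors()]
    double_o = any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(atom).GetSymbol() == "O"
        for b in atom.GetBonds()
    )
    if double_o:
        return 172.0 if ("O" in nbr_syms or "N" in nbr_syms) else 198.0
    if atom.GetIsAromatic():
        return 128.0
    if "O" in nbr_syms:
        return 62.0
    if "N" in nbr_syms:
        return 46.0
    if "Cl" in nbr_syms:
        return 42.0
    return 12.0 + 6.0 * atom.GetDegree()


def _h1_base_shift(mol: Chem.Mol, idx: int) -> float:
    """Shift of hydrogens attached to heavy atom `idx`."""
    atom = mol.GetAtomWithIdx(idx)
    sym = atom.GetSymbol()
    if sym == "O":
        return 2.6
    if sym == "N":
        return 1.9
    nbr_syms = [n.GetSymbol() for n in atom.GetNeighbors()]
    double_o = any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(atom).GetSymbol() == "O"
        for b in atom.GetBonds()
    )
    if double_o:
        return 9.7
    if atom.GetIsAromatic():
        return 7.3
    if "O" in nbr_syms:
        return 3.8
    if "Cl" in nbr_syms:
        return 3.6
    if "N" in nbr_syms:
        return 2.9
    if any(n.GetIsAromatic() for n in atom.GetNeighbors()):
        return 2.4
    return 1.3


_IR_GROUP_BANDS = [
    # (SMARTS, center cm-1, width, depth)
    ("[OX2H]", 3300.0, 120.0, 0.85),
    ("[NX3;H1,H2]", 3400.0, 90.0, 0.6),
    ("[CX4;H1,H2,H3]", 2920.0, 60.0, 0.5),
    ("[CX3]=[OX1]", 1715.0, 30.0, 0.9),
    ("c", 1600.0, 25.0, 0.45),
    ("c[H]", 3055.0, 40.0, 0.3),
    ("[#6][OX2]", 1105.0, 40.0, 0.6),
    ("[#6]Cl", 745.0, 30.0, 0.55),
    ("[#6]=[#6]", 1650.0, 25.0, 0.4),
    ("[#6]#[#6,#7]", 2220.0, 25.0, 0.5),
]
_IR_SMARTS = [(Chem.MolFromSmarts(s), c, w, d) for s, c, w, d in _IR_GROUP_BANDS]


def simulate_peaklists(record: MoleculeRecord | str) -> dict[str, object]:
    """Deterministic toy peak lists for all four modalities.

    ¹³C: one peak per symmetry-distinct carbon, position from the environment
    table plus a hashed offset (±6 ppm). ¹H: one multiplet per distinct
    hydrogen-bearing environment, intensity proportional to hydrogen count.
    IR: one band per functional group present plus three hashed fingerprint
    bands in 800–1500 cm⁻¹. HSQC: one peak per C–H pair of environments.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {smiles!r}")
    classes = _symmetry_classes(mol)

    # one representative atom per symmetry class
    class_rep: dict[int, int] = {}
    class_members: dict[int, list[int]] = {}
    for idx, cls in enumerate(classes):
        class_rep.setdefault(cls, idx)
        class_members.setdefault(cls, []).append(idx)

    c13_pos, c13_int = [], []
    h1_pos, h1_int, h1_wid = [], [], []
    hsqc_peaks: list[HSQCPeak] = []

    for cls, rep in sorted(class_rep.items()):
        atom = mol.GetAtomWithIdx(rep)
        members = class_members[cls]
        env = _atom_environment(mol, rep)
        if atom.GetSymbol() == "C":
            shift = _c13_base_shift(mol, rep) + 12.0 * (_hash_unit("c13|" + env) - 0.5)
            shift = float(np.clip(shift, 0.5, 299.5))
            c13_pos.append(shift)
            c13_int.append(len(members))
        n_h = atom.GetTotalNumHs()
        if n_h > 0:
            h_shift = _h1_base_shift(mol, rep) + 0.8 * (_hash_unit("h1|" + env) - 0.5)
            h_shift = float(np.clip(h_shift, -1.8, 9.9))
            h1_pos.append(h_shift)
            h1_int.append(float(n_h * len(members)))
            h1_wid.append(0.03)
            if atom.GetSymbol() == "C":
                c_shift = c13_pos[-1]
                hsqc_peaks.append(
                    HSQCPeak(
                        c_centroid=c_shift, c_min=c_shift - 1.0, c_max=c_shift + 1.0,
                        h_centroid=h_shift, h_min=h_shift - 0.05, h_max=h_shift + 0.05,
                    )
                )

    ir_pos, ir_int, ir_wid = [], [], []
    for patt, center, width, depth in _IR_SMARTS:
        if patt is not None and mol.HasSubstructMatch(patt):
            ir_pos.append(center)
            ir_int.append(depth)
            ir_wid.append(width)
    # hashed fingerprint-region bands make IR discriminative between molecules
    canonical = Chem.MolToSmiles(mol)
    for k in range(3):
        u = _hash_unit(f"ir|{canonical}|{k}")
        ir_pos.append(800.0 + 700.0 * u)
        ir_int.append(0.3 + 0.4 * _hash_unit(f"ird|{canonical}|{k}"))
        ir_wid.append(25.0)

    return {
        "c13": PeakList1D("c13", np.array(c13_pos), np.array(c13_int, dtype=float),
                          np.full(len(c13_pos), 0.5)),
        "h1": PeakList1D("h1", np.array(h1_pos), np.array(h1_int), np.array(h1_wid)),
        "ir": PeakList1D("ir", np.array(ir_pos), np.array(ir_int), np.array(ir_wid)),
        "hsqc": hsqc_peaks,
    }


def simulate_spectra(
    record: MoleculeRecord | str,
    modalities=MODALITIES,
    seed: int = 0,
    augment: AugmentationConfig | None = None,
    config: CodecConfig | None = None,
) -> SpectrumSet:
    """Vectorized toy spectra for the requested modalities.

    Pure function of (structure, seed, config): the peak lists are
    deterministic from the structure, and any augmentation noise is drawn
    from a generator seeded by `seed`.
    """
    if not modalities:
        raise ValueError("at least one modality must be requested")
    cfg = config or CodecConfig()
    peaklists = simulate_peaklists(record)
    vectors: dict[str, SpectrumVector] = {}
    for mod in modalities:
        if mod == "c13":
            vectors[mod] = bin_c13(peaklists["c13"], cfg)
        elif mod == "h1":
            pk = peaklists["h1"]
            if augment is not None:
                pk = augment_h1(pk, augment.with_seed(seed * 4 + 1))
            vec = vectorize_h1(pk, cfg)
            if augment is not None:
                vec = augment_h1(vec, augment.with_seed(seed * 4 + 2))
            vectors[mod] = vec
        elif mod == "ir":
            vectors[mod] = vectorize_ir(peaklists["ir"], cfg)
        elif mod == "hsqc":
            aug = (augment or AugmentationConfig.identity()).with_seed(seed * 4 + 3)
            vectors[mod] = rasterize_hsqc(peaklists["hsqc"], aug, cfg)
        else:
            raise ValueError(f"unknown modality {mod!r}")
    return SpectrumSet(vectors)
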