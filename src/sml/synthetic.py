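"""Synthetic molecule sets with the statistical structure the method assumes.

The generator emits SMILES in three structural classes (saturated; single
unsaturated; aromatic / poly-unsaturated carbonyl), 3-D geometries by
distance-geometry embedding, and HOMO/LUMO/gap labels whose pooled
distribution is trimodal: each class contributes a Gaussian mode, ordered
so the saturated class has the largest gaps, plus a smooth class-specific
function of the representation vector so that kernel models can learn
within-class structure. A second, correlated level of theory is derived
from the first for Δ-ML experiments.

This is not a quantum-property emulator: labels are statistical stand-ins
whose only claims are trimodality, within-class smoothness, the
gap ≡ LUMO − HOMO identity, and cross-level correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.stats import norm

from .chemdata import Dataset, Molecule, PropertyRecord
from .classify import ClassLabel
from .represent import (
    RepresentationBasis,
    RepresentationConfig,
    build_basis,
    representation_matrix,
)

__all__ = [
    "GeneratorParams",
    "SyntheticBenchmark",
    "gen_class_smiles",
    "gen_geometries",
    "gen_labels",
    "gen_two_level",
    "make_benchmark",
]

_VALENCE = {"C": 4, "N": 3, "O": 2}

#: Level-of-theory names attached to generated records.
TARGET_LEVEL = "target"
BASELINE_LEVEL = "baseline"


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic study conditions.

    Class gap means (9.5, 7.0, 5.0) eV with spreads (0.5, 0.6, 0.7) eV give a
    clearly separated trimodal mixture with the saturated class at the top.
    ``smooth_weight`` scales the representation-tied label component (the
    learnable part); ``noise_sd`` is irreducible label noise. The baseline
    level is an affine map of the target gap plus noise.
    """

    n_per_class: tuple[int, int, int] = (500, 500, 500)
    class_gap_means: tuple[float, float, float] = (9.5, 7.0, 5.0)
    class_gap_sds: tuple[float, float, float] = (0.5, 0.6, 0.7)
    smooth_weight: float = 1.0
    noise_sd: float = 0.05
    baseline_offset: float = -1.0
    baseline_slope: float = 1.0
    baseline_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("each class needs at least one molecule")
        m = self.class_gap_means
        if not (m[0] > m[1] > m[2]):
            raise ValueError("class gap means must decrease from class I to III")
        if any(s <= 0 for s in self.class_gap_sds):
            raise ValueError("class gap spreads must be positive")
        if self.noise_sd < 0 or self.baseline_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")


# ---------------------------------------------------------------------------
# SMILES generation
# ---------------------------------------------------------------------------

def _random_saturated_tree(rng: np.random.Generator, n_heavy: int,
                           carbon_only: bool = False) -> str:
    """Random acyclic saturated skeleton; heteroatoms (O, N) only bond to
    carbon, so every bond is single and the result is class I by
    construction. ``carbon_only`` restricts to pure alkyl trees."""
    symbols = ["C"]
    free = [_VALENCE["C"]]
    edges: list[tuple[int, int]] = []
    for i in range(1, n_heavy):
        open_slots = [j for j, f in enumerate(free) if f > 0]
        parent = int(rng.choice(open_slots))
        if carbon_only or symbols[parent] != "C":
            sym = "C"
        else:
            sym = str(rng.choice(["C", "C", "C", "C", "O", "N"]))
        symbols.append(sym)
        free[parent] -= 1
        free.append(_VALENCE[sym] - 1)
        edges.append((parent, i))
    mol = Chem.RWMol()
    for sym in symbols:
        mol.AddAtom(Chem.Atom(sym))
    for a, b in edges:
        mol.AddBond(a, b, Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


def _random_group(rng: np.random.Generator, n_min: int = 1, n_max: int = 6) -> str:
    """Random alkyl substituent for template assembly by string concatenation.

    Carbon-only keeps attachments valence-safe (the first and last written
    atoms of an acyclic alkyl SMILES always have a free valence) and ensures
    a group can never turn a template's carbonyl into an ester or amide.
    """
    n = int(rng.integers(n_min, n_max + 1))
    return _random_saturated_tree(rng, n, carbon_only=True)


def _canonical(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def _class_i(rng: np.random.Generator) -> str:
    return _random_saturated_tree(rng, int(rng.integers(4, 10)))


def _class_ii(rng: np.random.Generator) -> str:
    g = lambda: _random_group(rng)
    maybe = lambda p=0.5: _random_group(rng) if rng.random() < p else ""
    kind = rng.choice(
        ["alkene", "alkyne", "carbonyl", "amide", "ester", "amino_acid"],
        p=[0.3, 0.15, 0.25, 0.12, 0.12, 0.06],
    )
    if kind == "alkene":
        return f"{maybe(0.8)}C=C{maybe(0.8)}"
    if kind == "alkyne":
        return f"{maybe(0.8)}C#C{maybe(0.5)}"
    if kind == "carbonyl":          # lone ketone/aldehyde: branch (5), n_u = 1
        return f"{maybe(0.7)}C(=O){g()}"
    if kind == "amide":
        return f"{maybe(0.7)}C(=O)N{maybe(0.7)}"
    if kind == "ester":             # empty tail -> carboxylic acid, still branch (2)
        return f"{g()}C(=O)O{maybe(0.6)}"
    side = maybe(0.7)
    return f"NC({side})C(=O)O" if side else "NCC(=O)O"


_AROMATIC_CORES = ["c1ccccc1", "c1ccncc1", "c1ccoc1", "c1cc[nH]c1"]


def _class_iii(rng: np.random.Generator) -> str:
    g = lambda: _random_group(rng)
    maybe = lambda p=0.5: _random_group(rng) if rng.random() < p else ""
    if rng.random() < 0.6:  # aromatic branch (3); substituents saturated only
        core = str(rng.choice(_AROMATIC_CORES))
        if core == "c1ccccc1" and rng.random() < 0.6:
            para = maybe(0.6)
            return f"{g()}c1ccc({para})cc1" if para else f"{g()}c1ccccc1"
        return f"{maybe(0.7)}{core}"
    # poly-unsaturated carbonyl, branch (4): n_u >= 2, carbonyl C bonded to C/H only
    kind = rng.choice(["enone", "dione", "dienal"])
    if kind == "enone":
        return f"{maybe(0.7)}C(=O)C=C{maybe(0.7)}"
    if kind == "dione":
        return f"{maybe(0.7)}C(=O){g()}C(=O){maybe(0.5)}"
    return f"{maybe(0.6)}C=CC(=O)C=C{maybe(0.6)}"


def gen_class_smiles(params: GeneratorParams) -> list[tuple[str, ClassLabel]]:
    """Draw canonical, de-duplicated SMILES per class; deterministic in seed.

    Every decision branch of the classifier is represented: class I via
    random saturated skeletons, class II via single alkene/alkyne/lone
    carbonyl compounds and via amides/esters/acids/amino acids, class III via
    decorated aromatics and poly-unsaturated carbonyls.
    """
    rng = np.random.default_rng(params.seed)
    builders = [_class_i, _class_ii, _class_iii]
    labels = list(ClassLabel)
    seen: set[str] = set()
    out: list[tuple[str, ClassLabel]] = []
    for builder, label, count in zip(builders, labels, params.n_per_class):
        produced = 0
        attempts = 0
        while produced < count:
            attempts += 1
            if attempts > 200 * count:
                raise RuntimeError(f"could not generate {count} unique molecules for {label}")
            can = _canonical(builder(rng))
            if can is None or can in seen:
                continue
            seen.add(can)
            out.append((can, label))
            produced += 1
    return out


# ---------------------------------------------------------------------------
# Geometries
# ---------------------------------------------------------------------------

def gen_geometries(
    smiles_list: Sequence[str], seed: int, jitter_sd: float = 0.02,
    id_prefix: str = "syn",
) -> list[Molecule]:
    """Deterministic 3-D structures: distance-geometry embedding (ETKDG) with
    a per-molecule derived seed, hydrogens explicit, plus Gaussian coordinate
    jitter of ``jitter_sd`` Å."""
    rng = np.random.default_rng(seed)
    out: list[Molecule] = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        molh = Chem.AddHs(mol)
        ps = AllChem.ETKDGv3()
        ps.randomSeed = int((seed * 100003 + i * 7919) % (2**31 - 1)) + 1
        conf_id = AllChem.EmbedMolecule(molh, ps)
        if conf_id < 0:  # rare fallback for hard topologies
            ps.useRandomCoords = True
            conf_id = AllChem.EmbedMolecule(molh, ps)
        if conf_id < 0:
            raise RuntimeError(f"embedding failed for {smi!r}")
        coords = molh.GetConformer(conf_id).GetPositions()
        if jitter_sd > 0:
            coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
        else:
            rng.normal(0.0, 1.0, coords.shape)  # keep the stream aligned
        out.append(
            Molecule(
                id=f"{id_prefix}_{i:05d}",
                smiles=smi,
                elements=[a.GetSymbol() for a in molh.GetAtoms()],
                coords=coords,
                charges=[a.GetAtomicNum() for a in molh.GetAtoms()],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def gen_labels(
    molecules: Sequence[Molecule],
    class_map: dict[str, ClassLabel],
    reps: np.ndarray,
    params: GeneratorParams,
    level: str = TARGET_LEVEL,
) -> list[PropertyRecord]:
    """Class-conditional smooth gap labels with consistent HOMO/LUMO.

    Per class c: gap_i = mean_c + smooth_weight · 2·sd_c·tanh(z_i/2) + ε,
    where z_i is a normal-scores transform (monotone, Gaussianizing) of the
    molecule's projection of its representation on a seeded random direction
    (one direction per class) and ε is Gaussian label noise. The tanh
    squashes the smooth component to ±2 sd_c; the normal scores keep each
    class's gap distribution unimodal even when a class mixes structural
    sub-families whose projections separate. HOMO is anchored at
    −(gap/2 + 4 eV) and LUMO = HOMO + gap, so the gap identity holds exactly.
    """
    reps = np.asarray(reps, dtype=float)
    if reps.shape[0] != len(molecules):
        raise ValueError("one representation row per molecule required")
    rng = np.random.default_rng(params.seed + 1_000_003)
    labels = list(ClassLabel)
    cls_idx = {lab: [] for lab in labels}
    for i, mol in enumerate(molecules):
        cls_idx[class_map[mol.id]].append(i)

    gaps = np.empty(len(molecules))
    for lab, mean, sd in zip(labels, params.class_gap_means, params.class_gap_sds):
        idx = np.array(cls_idx[lab], dtype=int)
        w = rng.normal(size=reps.shape[1])
        w /= np.linalg.norm(w)
        if len(idx) == 0:
            continue
        proj = reps[idx] @ w
        ranks = np.argsort(np.argsort(proj, kind="stable"), kind="stable")
        z = norm.ppf((ranks + 0.5) / len(idx))
        smooth = 2.0 * sd * np.tanh(z / 2.0)
        noise = rng.normal(0.0, params.noise_sd, len(idx)) if params.noise_sd > 0 else 0.0
        gaps[idx] = mean + params.smooth_weight * smooth + noise

    records = []
    for mol, gap in zip(molecules, gaps):
        homo = -(gap / 2.0 + 4.0)
        records.append(
            PropertyRecord(molecule_id=mol.id, level=level,
                           homo=homo, lumo=homo + gap, gap=gap)
        )
    return records


def gen_two_level(
    records: Sequence[PropertyRecord],
    params: GeneratorParams,
    level: str = BASELINE_LEVEL,
) -> list[PropertyRecord]:
    """Correlated lower-level records: gap_b = slope·gap_t + offset + noise,
    with HOMO/LUMO reconstructed from the baseline gap by the same anchoring
    (keeps the gap identity exact at both levels)."""
    rng = np.random.default_rng(params.seed + 2_000_003)
    out = []
    for rec in records:
        gap_t = rec.get("gap")
        noise = rng.normal(0.0, params.baseline_noise_sd) if params.baseline_noise_sd > 0 else 0.0
        gap_b = params.baseline_slope * gap_t + params.baseline_offset + noise
        homo = -(gap_b / 2.0 + 4.0)
        out.append(
            PropertyRecord(molecule_id=rec.molecule_id, level=level,
                           homo=homo, lumo=homo + gap_b, gap=gap_b)
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end benchmark assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBenchmark:
    """A ready-to-use synthetic study: dataset, classes and representations."""

    dataset: Dataset
    class_map: dict[str, ClassLabel]
    X: np.ndarray                       # spectral representations, row per molecule
    basis: RepresentationBasis
    config: RepresentationConfig
    params: GeneratorParams


def make_benchmark(
    params: Optional[GeneratorParams] = None,
    rep_config: Optional[RepresentationConfig] = None,
) -> SyntheticBenchmark:
    """Generate molecules, geometries, representations and two-level labels."""
    params = params or GeneratorParams()
    rep_config = rep_config or RepresentationConfig()
    pairs = gen_class_smiles(params)
    mols = gen_geometries([s for s, _ in pairs], seed=params.seed)
    class_map = {mol.id: lab for mol, (_s, lab) in zip(mols, pairs)}
    dataset = Dataset(molecules=mols)
    X, basis = representation_matrix(dataset, config=rep_config)
    for rec in gen_labels(mols, class_map, X, params):
        dataset.add_record(rec)
    target_records = [dataset.record(m.id, TARGET_LEVEL) for m in mols]
    for rec in gen_two_level(target_records, params):
        dataset.add_record(rec)
    return SyntheticBenchmark(
        dataset=dataset, class_map=class_map, X=X, basis=basis,
        config=rep_config, params=params,
    )
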