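"""Fixed-length molecular representations from composition and geometry.

The workhorse is a spectral many-body representation in the SLATM family:
the concatenation of a one-body block (nuclear charge times element count),
two-body radial spectra (London-dispersion-weighted Gaussians of interatomic
distances on a radial grid, one channel per element pair) and three-body
angular spectra (charge-weighted Gaussians of the central angle, one channel
per element triple with the center distinguished). The result is invariant
to translation, rotation and atom ordering by construction, since it only
consumes internal distances and angles.

A sorted Coulomb-matrix eigenvalue spectrum is provided as the lightweight
heuristic alternative.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chemdata import Dataset, Molecule

__all__ = [
    "RepresentationConfig",
    "RepresentationBasis",
    "RepVector",
    "build_basis",
    "slatm_vector",
    "coulomb_eigs",
    "representation_matrix",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class RepresentationConfig:
    """Grid and smearing hyperparameters of the spectral representation.

    Defaults are conventional for small organics: a radial grid covering
    bonded through long-range distances at 0.05 Å resolution with matching
    Gaussian width, 40 angular bins over [0, π], and a 4.8 Å neighbor cutoff
    for the three-body terms.
    """

    r_min: float = 0.2      # Å
    r_max: float = 8.0      # Å
    dr: float = 0.05        # Å
    sigma_r: float = 0.05   # Å
    theta_bins: int = 40
    sigma_theta: float = 0.05  # rad
    r_cut: float = 4.8      # Å

    def __post_init__(self) -> None:
        if not (self.r_min < self.r_max):
            raise ValueError("require r_min < r_max")
        if self.dr <= 0 or self.sigma_r <= 0 or self.sigma_theta <= 0:
            raise ValueError("grid step and Gaussian widths must be positive")
        if self.theta_bins < 1:
            raise ValueError("theta_bins must be at least 1")

    @property
    def n_r_bins(self) -> int:
        return int(round((self.r_max - self.r_min) / self.dr))

    def r_grid(self) -> np.ndarray:
        """Radial bin centers."""
        return self.r_min + self.dr * (np.arange(self.n_r_bins) + 0.5)

    def theta_grid(self) -> np.ndarray:
        """Angular bin centers over [0, π]."""
        dt = np.pi / self.theta_bins
        return dt * (np.arange(self.theta_bins) + 0.5)

    @property
    def dtheta(self) -> float:
        return np.pi / self.theta_bins


@dataclass(frozen=True)
class RepresentationBasis:
    """Canonical channel ordering shared by every molecule of a dataset.

    ``elements`` are ascending nuclear charges; ``pairs`` are unordered charge
    pairs (z1 ≤ z2, lexicographic); ``triples`` are (center, flank_lo,
    flank_hi) with the central element distinguished, lexicographic.
    """

    elements: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]
    triples: tuple[tuple[int, int, int], ...]

    def vector_length(self, config: RepresentationConfig) -> int:
        return (
            len(self.elements)
            + len(self.pairs) * config.n_r_bins
            + len(self.triples) * config.theta_bins
        )


@dataclass
class RepVector:
    """A molecule's representation vector plus the basis/config that shaped it."""

    values: np.ndarray
    basis: Optional[RepresentationBasis] = None
    config: Optional[RepresentationConfig] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("representation vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def build_basis(dataset: Dataset) -> RepresentationBasis:
    """Union of element, pair and triple channels over all molecules.

    Channels are formed combinatorially from each molecule's element set, so
    a CH4-only dataset yields pairs (1,1), (1,6), (6,6) even though no two
    carbons coexist; the ordering is canonical and independent of molecule
    order.
    """
    if len(dataset) == 0:
        raise ValueError("cannot build a representation basis from an empty dataset")
    elements: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    triples: set[tuple[int, int, int]] = set()
    for mol in dataset.molecules:
        zs = sorted(set(mol.charges))
        elements.update(zs)
        for a, b in itertools.combinations_with_replacement(zs, 2):
            pairs.add((a, b))
        for center in zs:
            for a, b in itertools.combinations_with_replacement(zs, 2):
                triples.add((center, a, b))
    return RepresentationBasis(
        elements=tuple(sorted(elements)),
        pairs=tuple(sorted(pairs)),
        triples=tuple(sorted(triples)),
    )


def _gaussian(grid: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Normalized Gaussians: rows = centers, columns = grid."""
    d = grid[None, :] - centers[:, None]
    return np.exp(-0.5 * (d / sigma) ** 2) / (sigma * _SQRT_2PI)


def slatm_vector(
    mol: Molecule, basis: RepresentationBasis, config: Optional[RepresentationConfig] = None
) -> RepVector:
    """Spectral 1-/2-/3-body representation of one molecule.

    One-body: per element, atom count × nuclear charge. Two-body, per pair
    channel: Σ over matching atom pairs of ½·Z_i·Z_j/r_ij⁶ · dr · N(r; r_ij,
    σ_r) on the radial grid. Three-body, per (center, flanks) channel: Σ over
    triplets whose arms both lie within r_cut of the center of
    Z_i·Z_j·Z_k/3 · dθ · N(θ; θ_ijk, σ_θ) on the angular grid, with θ the
    angle at the central atom.
    """
    config = config or RepresentationConfig()
    z = np.asarray(mol.charges, dtype=int)
    missing = sorted(set(z) - set(basis.elements))
    if missing:
        raise ValueError(f"element(s) with charge {missing} absent from basis")

    n_r = config.n_r_bins
    r_grid = config.r_grid()
    t_grid = config.theta_grid()
    pair_index = {p: i for i, p in enumerate(basis.pairs)}
    triple_index = {t: i for i, t in enumerate(basis.triples)}

    one = np.array([float(e * np.sum(z == e)) for e in basis.elements])
    two = np.zeros((len(basis.pairs), n_r))
    three = np.zeros((len(basis.triples), config.theta_bins))

    xyz = mol.coords
    n = len(z)
    if n >= 2:
        diff = xyz[:, None, :] - xyz[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        rij = dist[iu, ju]
        if np.any(rij == 0):
            raise ValueError(f"molecule {mol.id!r}: coincident atoms")
        chan = np.array([pair_index[(min(a, b), max(a, b))]
                         for a, b in zip(z[iu], z[ju])])
        amp = 0.5 * z[iu] * z[ju] / rij**6 * config.dr
        g = _gaussian(r_grid, rij, config.sigma_r) * amp[:, None]
        np.add.at(two, chan, g)

    if n >= 3:
        for j in range(n):
            nbrs = np.where((dist[j] <= config.r_cut) & (np.arange(n) != j))[0]
            if len(nbrs) < 2:
                continue
            ia, ka = np.triu_indices(len(nbrs), k=1)
            a_idx, b_idx = nbrs[ia], nbrs[ka]
            va = xyz[a_idx] - xyz[j]
            vb = xyz[b_idx] - xyz[j]
            cos = np.sum(va * vb, axis=1) / (dist[j, a_idx] * dist[j, b_idx])
            theta = np.arccos(np.clip(cos, -1.0, 1.0))
            lo = np.minimum(z[a_idx], z[b_idx])
            hi = np.maximum(z[a_idx], z[b_idx])
            chan = np.array([triple_index[(z[j], a, b)] for a, b in zip(lo, hi)])
            amp = z[a_idx] * z[j] * z[b_idx] / 3.0 * config.dtheta
            g = _gaussian(t_grid, theta, config.sigma_theta) * amp[:, None]
            np.add.at(three, chan, g)

    values = np.concatenate([one, two.ravel(), three.ravel()])
    return RepVector(values=values, basis=basis, config=config)


def coulomb_eigs(mol: Molecule, n_max: int) -> RepVector:
    """Sorted Coulomb-matrix eigenvalue spectrum, zero-padded to ``n_max``.

    M_ii = 0.5·Z_i^2.4, M_ij = Z_i·Z_j/r_ij (Å); eigenvalues ordered by
    descending absolute value. Permutation-invariant by construction.
    """
    n = mol.n_atoms
    if n < 1:
        raise ValueError("molecule has no atoms")
    if n_max < n:
        raise ValueError(f"n_max={n_max} smaller than atom count {n}")
    z = np.asarray(mol.charges, dtype=float)
    diff = mol.coords[:, None, :] - mol.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0):
        raise ValueError(f"molecule {mol.id!r}: coincident atoms")
    m = np.zeros((n, n))
    m[off] = np.outer(z, z)[off] / dist[off]
    np.fill_diagonal(m, 0.5 * z**2.4)
    eigs = np.linalg.eigvalsh(m)
    eigs = eigs[np.argsort(-np.abs(eigs), kind="stable")]
    return RepVector(values=np.concatenate([eigs, np.zeros(n_max - n)]))


def representation_matrix(
    dataset: Dataset,
    basis: Optional[RepresentationBasis] = None,
    config: Optional[RepresentationConfig] = None,
    cache: Optional[Path] = None,
) -> tuple[np.ndarray, RepresentationBasis]:
    """Stack the spectral representation of every molecule into one matrix.

    Rows follow ``dataset.molecules`` order. When ``cache`` (a directory) is
    given, the matrix is memoized on disk keyed by a hash of geometries,
    basis and config.
    """
    basis = basis or build_basis(dataset)
    config = config or RepresentationConfig()
    key = None
    if cache is not None:
        h = hashlib.sha256()
        for mol in dataset.molecules:
            h.update(mol.id.encode())
            h.update(np.ascontiguousarray(mol.coords).tobytes())
            h.update(np.asarray(mol.charges).tobytes())
        h.update(repr(basis).encode())
        h.update(repr(config).encode())
        key = Path(cache) / f"slatm_{h.hexdigest()[:16]}.npy"
        if key.exists():
            return np.load(key), basis
    x = np.vstack([slatm_vector(m, basis, config).values for m in dataset.molecules])
    if key is not None:
        key.parent.mkdir(parents=True, exist_ok=True)
        np.save(key, x)
    return x, basis
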