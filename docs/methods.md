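# Methods

## The problem

HOMO–LUMO gaps of small organic molecules are intensive electronic
properties and notoriously data-hungry targets for kernel-based surrogate
models: structurally similar molecules can have very different gaps, because
the pooled gap distribution is a superposition of several chemical
sub-populations. Over typical small-organic datasets it is trimodal, with
modes carried by (I) fully saturated molecules at the largest gaps, (II)
molecules with a single unsaturated bond in the middle, and (III) aromatic
and poly-unsaturated carbonyl compounds at the smallest gaps.

Selected machine learning (SML) exploits this: classify every molecule by a
handful of substructure rules *before* training, then train one independent
kernel ridge regression (KRR) model per class. Each model then faces a
unimodal, smoother structure→label map, which empirically lowers
learning-curve offsets at unchanged slopes — the same accuracy from up to an
order of magnitude fewer training molecules.

## Classification rules

Structural tags are computed from SMILES by SMARTS substructure matching
(RDKit, default aromaticity perception after sanitization):

| tag | pattern |
|---|---|
| carbonyl | `[CX3]=[OX1]` |
| amide | `[NX3][CX3]=[OX1]` |
| carboxylic acid / ester | `[OX2][CX3]=[OX1]` |
| amino acid | `[NX3;!$(N-C=O)][CX4][CX3](=[OX1])[OX2H1,OX1-]` |

`n_u` counts every double, triple or aromatic bond between heavy atoms once
(benzene: 6; C=O bonds count). The decision sequence is:

1. `n_u == 0` → **class I** (saturated);
2. amide, acid/ester, or amino acid → **class II** — these carbonyl
   sub-families sit near the middle mode even when poly-unsaturated, so
   they are routed before the aromatic test (this also fixes the otherwise
   ambiguous aromatic-amide case: it goes to class II);
3. aromatic → **class III**;
4. carbonyl with `n_u > 1` → **class III**;
5. everything else → **class II**.

The function is total and single-valued for every parseable SMILES, and
`n_u == 0 ⇔ class I` by construction.

A structure-free baseline (`gmm_baseline`) fits a 1-D Gaussian mixture to
the gap values alone (EM, 10 restarts, tolerance 1e−8, components relabeled
by ascending mean); the frequency analysis (`frequency_analysis`) decomposes
the gap distribution per tag with Gaussian KDEs of fixed absolute bandwidth
(default 0.15 eV) scaled so each curve integrates to the tag's share of the
dataset. The evaluation grid spans the pooled gap range padded by six
bandwidths: three would truncate up to ~0.3 % of a full-coverage tag's
kernel mass and break the integral-equals-weight property at its stated
1e−3 tolerance.

## Representation

The default representation is a spectral many-body vector in the SLATM
family, built per dataset from a canonical channel basis (elements, element
pairs, element triples with the center distinguished, formed
combinatorially from each molecule's element set):

- 1-body, per element: atom count × nuclear charge;
- 2-body, per pair channel: Σ over matching atom pairs of
  ½·Z_i·Z_j/r_ij⁶ · dr · N(r; r_ij, σ_r) on a radial grid
  (defaults r ∈ [0.2, 8.0] Å, dr = σ_r = 0.05 Å);
- 3-body, per triple channel: Σ over triplets with both arms within
  r_cut = 4.8 Å of the central atom of
  (Z_i·Z_j·Z_k/3) · dθ · N(θ; θ_ijk, σ_θ) over 40 angular bins on [0, π]
  (σ_θ = 0.05 rad). The angular weight is a plain Gaussian in the central
  angle; the cosine-product modulation used by some variants of the scheme
  is deliberately omitted and the choice is config-exposed.

All inputs are internal distances and angles, so the vector is invariant
under translation, rotation and atom relabeling by construction (verified
to 1e−8 under random rigid transforms). A sorted Coulomb-matrix eigenvalue
spectrum (`coulomb_eigs`; diagonal 0.5·Z^2.4, off-diagonal Z_iZ_j/r_ij,
eigenvalues by descending magnitude, zero-padded) is available as the
cheap heuristic alternative.

## Regression

Laplacian kernel k(X, X′) = exp(−‖X − X′‖₁/σ); coefficients from
(K + λI)α = y via Cholesky factorization with automatic jitter escalation
(λ×10, at most 3 times, warning emitted) and a least-squares fallback.
λ = 1e−12 by default — the labels are noiseless, so regularization is a
numerical stabilizer only. σ is chosen per training set by seeded k-fold
(default 5) grid-search cross validation minimizing mean MAE, ties toward
the smaller σ.

The default σ grid is powers of two, 2⁴…2¹⁸. The upper end matters:
L1 distances between default spectral vectors of ~20-atom organics run
5×10³–10⁵ (the 3-body block dominates the norm), and a grid capped well
below the typical distance forces the kernel toward the identity, which
underfits catastrophically. Δ-ML experiments that must represent a nearly
constant correction use a wider grid (4²…4¹³ ≈ 1.7×10⁻²…6.7×10⁷): a
Laplacian-kernel model can only produce a constant over the data span when
σ greatly exceeds the typical distance (the off-sample error of a constant
fit scales like c·(1 − e^(−d/σ))/n).

## Experiment protocol

For each repetition (seeded `seed + rep`) one test set per class (default
200 molecules) is drawn first; every training draw excludes all test
molecules. Generic models draw uniformly from the remaining pool, selected
models from the class remainder; training sets are nested across sizes.
Generic and selected models of a class are always evaluated on the identical
test ids, making their MAEs directly comparable. Curves are averaged over
repetitions (default 10) and summarized by least-squares lines in
log10(MAE) vs log10(N_tr).

Δ-ML trains KRR on y_target − y_baseline and adds the predicted correction
back onto the baseline value of each test molecule.

## Synthetic study conditions

The generator produces 500 molecules per class by default (1500 total):

- class I: random acyclic saturated C/O/N skeletons of 4–9 heavy atoms
  (heteroatoms bond only to carbon);
- class II: one unsaturated feature — alkene, alkyne, lone ketone/aldehyde,
  amide, ester/acid, or amino-acid motif — decorated with random alkyl
  substituents;
- class III: decorated benzenes, pyridines, furans and pyrroles, plus
  non-aromatic poly-unsaturated carbonyls (enones, diones, dienals).

Substituent groups are pure alkyl so template assembly can never silently
change a molecule's class. Geometries come from RDKit ETKDG
distance-geometry embedding with a per-molecule seed derived from the master
seed, hydrogens explicit, plus 0.02 Å Gaussian jitter; this is deterministic
given the seed and replaces a fixed template table, which cannot cover a
combinatorial SMILES space.

Gap labels: gap_i = mean_c + w·2·sd_c·tanh(z_i/2) + ε, with
(mean_I, mean_II, mean_III) = (9.5, 7.0, 5.0) eV,
(sd_I, sd_II, sd_III) = (0.5, 0.6, 0.7) eV, smooth weight w = 1, label
noise ε ~ N(0, 0.05 eV), and z_i the within-class standardized projection of
the representation on one seeded random direction per class. The tanh bounds
the smooth component to ±2 sd, the class-specific directions make the
generic model's task genuinely harder than any single class's, and the
means/sds separate the modes by > 4 sd, mirroring the trimodal shape of real
small-organic gap distributions. HOMO is anchored at −(gap/2 + 4 eV) and
LUMO = HOMO + gap, so the gap identity holds exactly; only the identity, not
the anchor, is load-bearing. The second level applies
gap_b = slope·gap_t + offset + noise (defaults 1.0, −1.0 eV, 0.05 eV →
r ≈ 0.9996) to the gap and re-anchors HOMO/LUMO, because applying the affine
map to all three properties independently would break the gap identity.

What the fixtures do **not** emulate: real electronic structure (labels are
statistical), conformational flexibility, ring-rich or caged scaffolds,
class imbalance, and label noise correlated with structure. Passing tests
demonstrate the machinery and the qualitative SML mechanism, not
quantitative transfer to QM7b/QM9; full-scale runs require downloading those
sets and supplying them through `chemdata`.

## Problem sizes and numerical choices

Default experiment sizes — 1500 molecules, training sizes 16…256, 10
repetitions, 200 test molecules per class — keep a full comparison around a
minute on one CPU after representations are built, while leaving the
selected-vs-generic gap far larger than the repetition scatter. The full
pairwise L1 distance matrix is computed once per experiment and sliced per
cell. Degenerate inputs are handled explicitly: duplicate training rows fall
back to jitter/least-squares; coincident atoms, empty datasets, empty grids
and mismatched lengths raise informative errors; GMM fits refuse k larger
than the number of distinct values.

## Known limitations

- The 3-body angular weight is one member of a family of SLATM-like
  variants; absolute σ values and full-scale MAEs shift with this and with
  the grid/width settings (all config-exposed).
- The classifier trusts the aromaticity model of the underlying toolkit;
  perception differences across toolkits can relabel borderline rings.
- `run_learning_curve` with selection="selected" averages per-class MAEs
  with equal weights, which equals the pooled MAE only for equal-size test
  sets (the default).
- Learning-curve log-log fits assume the power-law regime; at the noise
  floor (label noise 0.05 eV) curves flatten and the fitted slope shrinks.
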