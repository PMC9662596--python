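# sml — selected machine learning of frontier-orbital energies

`sml` builds data-efficient kernel-ridge-regression (KRR) surrogates of
HOMO/LUMO energies and HOMO–LUMO gaps for small organic molecules. Gaps are
intensive electronic properties with a multimodal distribution over chemical
compound space, which makes a single generic model data-hungry. The package
implements **selected machine learning (SML)**: partition the molecules into
three chemically defined classes *before* training —

- **class I** — saturated (no double, triple or aromatic bond),
- **class II** — single unsaturated (plus amides, carboxylic acids/esters
  and amino acids),
- **class III** — aromatic and poly-unsaturated carbonyl compounds,

then train one independent KRR model per class. Each class carries one mode
of the gap distribution, so the per-class maps are smoother and the
learning curves show the characteristic *lower offset at unchanged slope*
compared with generic random training-set selection.

The model: ŷ(X) = Σ_j k(X, X_j)·α_j with the Laplacian kernel
k(X, X′) = exp(−‖X − X′‖₁/σ), coefficients from (K + λI)α = y (λ = 10⁻¹²,
σ by grid-search cross validation inside each training set). Molecules are
represented by a spectral 1-/2-/3-body (SLATM-style) vector computed from
composition and 3-D geometry, or by the Coulomb-matrix eigenvalue spectrum.
Δ-ML between two levels of theory (train on target − baseline, add the
predicted correction to the baseline) is included for comparison, and a
synthetic-data module generates trimodal benchmark sets so every part of
the pipeline runs without external downloads. QM7b/QM9-style data can be
supplied as extended XYZ and CSV/JSON-lines property tables.

Intended users: method developers and computational chemists studying
training-set selection and data-efficiency of QML models.

## Worked example

```python
from sml import (GeneratorParams, SplitSpec, classify_smiles,
                 fit_loglog, run_sml_comparison)
from sml.synthetic import make_benchmark

# one functional change walks a ring across all three gap modes
for smi in ("OC1CCCCC1", "OC1CCCC=C1", "Oc1ccccc1"):
    print(smi, classify_smiles(smi).short)

bench = make_benchmark(GeneratorParams(seed=1))      # 1500 molecules
spec = SplitSpec(train_sizes=(16, 32, 64, 128, 256),
                 test_size_per_class=200, repetitions=10, seed=1)
pairs = run_sml_comparison(bench.dataset, None, spec, ("gap", "target"),
                           class_map=bench.class_map,
                           representations=bench.X)
for cls, (generic, selected) in pairs.items():
    off_g, slope_g = fit_loglog(generic)
    off_s, slope_s = fit_loglog(selected)
    print(f"class {cls.short}: MAE@256 generic {generic.mae_mean[-1]:.3f} eV,"
          f" selected {selected.mae_mean[-1]:.3f} eV,"
          f" offset drop {off_g - off_s:.3f}, slopes {slope_g:.2f}/{slope_s:.2f}")
```

Output (seed 1):

```
OC1CCCCC1 I
OC1CCCC=C1 II
Oc1ccccc1 III
class I: MAE@256 generic 0.448 eV, selected 0.217 eV, offset drop 0.762, slopes -0.35/-0.16
class II: MAE@256 generic 0.325 eV, selected 0.085 eV, offset drop 0.592, slopes -0.25/-0.25
class III: MAE@256 generic 0.421 eV, selected 0.135 eV, offset drop 0.594, slopes -0.32/-0.29
```

Reading: at 256 training molecules every class model beats the generic
model trained on the same number of randomly drawn molecules (by 2–3× in
MAE), and the log–log fits show the gain is an offset drop at similar
slope — the classification buys data-efficiency, not a different learning
exponent. The same experiment is available from the shell:

```bash
sml --seed 1 synth --n 500 500 500 --out bench/
sml --seed 1 compare --dir bench/ --out curves.csv
sml --seed 1 delta --dir bench/ --out delta.csv
```

Every run writes a `manifest.json` (config echo, seed, library versions)
sufficient to reproduce it.

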