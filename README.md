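# como-design

Quantitative diagnostics of chemical saturation and SAR progression for
analog series, combined with Free-Wilson (FW) driven design and potency
prediction of virtual analogs for series expansion and candidate
prioritization.

## What it does

Given an analog series (compounds sharing a core scaffold, differing only in
substituents at indexed sites, with logarithmic potencies pKi/pIC50):

* **Matched-molecular-pair (MMP) analysis** — single-cut fragmentation of
  eligible exocyclic single bonds identifies pairs of compounds distinguished
  by a substituent exchange at exactly one site; MMP-connected compounds are
  assembled into analog series with a common multi-site core
  (`como.chem`).
* **Saturation / progression diagnostics** — a population of virtual analogs
  (VAs, default 2000) is enumerated on the series core from a substituent
  pool, projected together with the existing analogs (EAs) into a 7-D
  z-normalized physicochemical descriptor space, and analyzed for membership
  in EA neighborhoods (Euclidean balls).  This yields the coverage score C,
  density score D, their harmonic-mean saturation score S, and the SAR
  progression score P (`como.diagnostics`).
* **Free-Wilson engine** — exhaustive search of the MMP network for FW
  neighborhoods (hub A with two single-site MMP edges at distinct sites),
  generation of the double-substituted target analogs (existing targets = FW
  EAs, novel ones = FW VAs), additive potency prediction
  `pot(X) = pot(B) + pot(C) - pot(A)` averaged over all neighborhoods of a
  target, and the FW-neighborhood saturation score
  `N = 1 - n_FW_EA / n_FW_NBH` (`como.fw`).
* **QSAR baselines** — ridge regression and epsilon-SVR with a Tanimoto
  kernel on 1024-bit ECFP4 fingerprints, evaluated with a double
  (internal 5-fold / external 20%) cross-validation protocol and the
  coefficient of determination R² (`como.qsar`).
* **Synthetic fixtures** — chemically valid analog series on a quinoline
  scaffold (1–6 inequivalent substitution sites) with exactly additive
  potency landscapes, optional pairwise interaction terms and Gaussian
  noise, plus a grammar-based substituent-pool generator
  (`como.synthetic`).

## CLI

```bash
# generate a synthetic analog series as a compound table
como simulate --out sim/ --seed 7

# C/D/S/P/N diagnostic scores per series (+ optional S-vs-P scatter)
como diagnose --series sim/compounds.csv --config config.yaml --out report/

# FW neighborhoods, FW EA benchmark predictions, N scores
como fw-analyze --series sim/compounds.csv --out report/

# generate FW VAs, predict potencies, rank candidates
como expand --series sim/compounds.csv --out report/ --with-svr

# ridge / Tanimoto-SVR double-CV benchmark
como qsar-benchmark --series sim/compounds.csv --out report/
```

Compound tables are CSV (`id,smiles,potency`), `.smi`
(`SMILES id` per line) or SDF (potency from a named property tag).  The
YAML config may set `n_va`, `radius`, `descriptors`, `seed`, `n_trials`,
`max_substituent_heavy_atoms` and `pool_size`; the resolved configuration is
written into every output directory.

## Layout

```
src/como/
  chem.py         MMP fragmentation, series assembly, de/recomposition, I/O
  diagnostics.py  VA enumeration, reference space, NBHs, C/D/S/P scores
  fw.py           FW neighborhoods, FW VA generation, prediction, N score
  qsar.py         fingerprints, ridge, Tanimoto-SVR, double CV, R²
  synthetic.py    synthetic series / substituent-pool generators
  cli.py          click command group (`como`)
tests/            unit, property and acceptance tests (pytest + hypothesis)
scripts/acceptance.py
```
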