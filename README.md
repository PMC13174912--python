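# calixtda

Topological descriptors and kernel-ridge surrogates for screening
calix[4]arene CO₂-capture candidates.

## The problem

Calix[4]arenes — cyclic tetramers of phenol units with a chalice-shaped
hydrophobic cavity — are tunable hosts for CO₂ physisorption, a candidate
chemistry for solid-sorbent direct air capture. Computing the adsorption
enthalpy

ΔH = H(host·CO₂) − H(host) − H(CO₂)   (kcal·mol⁻¹, 298.15 K)

by quantum chemistry for every member of a combinatorially functionalized
library is infeasible, so a surrogate model is trained on a labelled subset
and used to rank the rest. `calixtda` implements that workflow end to end
for users who have (or can generate) host geometries and a labelled subset:

1. **Enumeration** — symmetric tetra-functionalization of four macrocycle
   families (calix / aza / oxa / thia) with a valency-filtered substituent
   SMILES list, via RDKit.
2. **Topology** — Vietoris–Rips persistent homology of the host's atomic
   point cloud: H₀ bars (connectivity; minimum-spanning-tree merge heights)
   and H₁ bars (atom rings and transient holes; Z/2 boundary-matrix
   reduction), each tagged with the element pair of its defining edge. An
   exhaustive small-instance reduction oracle ships alongside for
   verification.
3. **Imaging** — elemental persistence images: bars become Gaussian bumps in
   the (birth, persistence) plane on 55×55 grids per homology order, with
   the kernel spread widened by the Pauling-electronegativity difference of
   the bar's edge atoms, σ_eff = σ·(1 + λ·|χ_a − χ_b|). Flattened H₀‖H₁
   grids give a 6050-long descriptor invariant to translation, rotation and
   atom reordering.
4. **Surrogate** — kernel ridge regression with the Laplacian kernel
   K(x,y) = exp(−γ‖x−y‖₁), dual coefficients from (K + αI)c = y, 3-fold
   cross-validated grid search with the one-standard-error rule (most
   regularized setting within one SE of the best mean test R²).
5. **Discovery** — rank candidates by predicted ΔH, draw a seeded
   stratified validation sample biased toward strong binders (default 3/3/5
   across strata split at −5 and −7 kcal·mol⁻¹), fold validated labels back
   in and re-run the hyperparameter search (dataset augmentation). Plus a
   geometric cone / partial-cone / 1,2-alternate / 1,3-alternate
   conformation classifier and box-plot-style (family × conformation)
   summaries.
6. **Fixtures** — deterministic synthetic calixarene-like geometries and
   pixel-linear enthalpy labels so the whole pipeline is testable without
   any quantum-chemistry data.

## Worked example

`examples/` holds one short script per capability. Training the surrogate
on 120 synthetic structures (`python examples/03_train_surrogate.py`):

```
120 structures, descriptor length 6050
labels: mean -5.04, sd 2.55 kcal/mol

selected: alpha=0.1, gamma=0.04642 (of 49 grid points)
train R2 0.993, test R2 0.985 +- 0.005
test RMSE 0.30 +- 0.04 kcal/mol, MAE 0.24 kcal/mol
```

The labels here are a known sparse linear functional of the image pixels
plus 0.3 kcal·mol⁻¹ noise; a test R² near 1 and RMSE near the noise floor
show the one-SE-selected kernel model recovers the planted enthalpy law.
`examples/01_persistence_of_a_ring.py` prints the bars of a benzene-sized
hexagon (five H₀ bars dying at the 1.4 Å bond length, one H₁ ring bar born
at 1.4 Å), and `examples/04_discovery_loop.py` runs one full
screen–validate–augment turn.

A thin CLI wraps the same calls:

```sh
calixtda enumerate --extras --out library.csv
calixtda fixtures --n 100 --seed 7 --out data/
calixtda train --manifest data/manifest.csv --xyz-dir data/ --out model/
calixtda screen --model model/ --pool data/ --sample 3,3,5 --seed 1 --out report.csv
```

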