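# Methods

## Model overview

`calixtda` builds a quantitative structure–property surrogate for the CO₂
adsorption enthalpy of calix[4]arene hosts. The featurization is purely
geometric-topological: the host's atoms are treated as a Euclidean point
cloud in Å, and the Vietoris–Rips filtration (balls of growing radius r
around each atom; cliques of the r-neighbourhood graph become simplices)
yields persistence bars in homological orders 0 and 1. H₀ bars encode when
connected components merge — at small r this recovers the bonding pattern,
at larger r through-space contacts — and H₁ bars encode cycles: the aryl
rings themselves and transient cavities of the chalice. The bars are
rasterized into persistence images and regressed against enthalpy with
kernel ridge regression. No electronic-structure information enters except
through the elemental spread modulation described below.

## Topology

* **H₀.** The finite bars are (0, w) for the n−1 minimum-spanning-tree edge
  weights w — identical to single-linkage dendrogram merge heights. A
  Kruskal sweep in (weight, lexicographic) order makes the merge-edge
  choice deterministic under ties and handles coincident atoms (zero-length
  edges). The essential bar of the single component is dropped from
  diagrams by default.
* **H₁.** Edges with length ≤ r_max and all triangles (filtration value =
  longest edge) are ordered by (value, dimension, vertex tuple); Z/2 column
  reduction pairs each reduced triangle with its youngest cycle-creating
  edge. Zero-persistence pairs are discarded: in a clique filtration any
  3-ring is filled the instant it appears, so only genuine holes survive.
  Cycle-creating edges never killed below r_max become bars with death =
  r_max and a `truncated` flag; downstream stages decide their treatment
  (the imaging default clips them to the window edge, keeping long-lived
  rings visible).
* **Element tagging.** Each bar carries the element pair of its defining
  edge: the merging edge for H₀, the cycle-creating (birth) edge for H₁.
  This is the hook for elemental weighting during imaging; where ties make
  the defining edge non-unique the deterministic simplex order picks one,
  which can only affect the tag, never the bar endpoints.
* **r_max = 7.0 Å** by default — twice the image window's upper bound — so
  features dying beyond the plotted window still register before clipping.
  The window bounds the descriptor, not the topology.
* **Hydrogens** are included by default (`TopoConfig.include_hydrogens`
  switches them off): the descriptor is defined on the full Cartesian point
  cloud, and dropping H is an auditable alternative rather than a silent
  default.
* **Oracle.** `calixtda.oracle.vr_bars_oracle` is a deliberately naive full
  boundary-matrix reduction over every simplex up to dimension 2 (dense
  numpy over GF(2), textbook left-to-right reduction, no union-find, no
  sparsity). It shares no code with the production path and is the
  reference the test suite compares against on ~100 random 5–12 point
  clouds per run; the acceptance script reports the agreement rate.

## Persistence images

Bars map to points (birth, persistence = death − birth), weighted by their
persistence (default) or uniformly, and are accumulated as isotropic
Gaussians on a per-order pixel grid spanning [−0.10, 3.5] Å at 55×55
resolution. Pixel value = weight × density at the pixel center × pixel
area — center-point quadrature, whose error is second order at this
resolution. The H₀ grid and H₁ grid are concatenated row-major into a
6050-vector.

Numerical and design choices:

* **Spread units.** The nominal Gaussian spread of 3.0 is interpreted in
  *pixel* units (σ_Å = 3.0 × (3.6 Å / 55) ≈ 0.196 Å). A literal 3.0 Å
  kernel would blur the entire 3.6 Å window into one blob and destroy all
  locality; `spread_units="angstrom"` restores the literal reading for
  comparison.
* **Elemental modulation.** σ_eff = σ·(1 + λ·|χ_a − χ_b|) with Pauling
  electronegativities (H 2.20, C 2.55, N 3.04, O 3.44, F 3.98, S 2.58) and
  λ = 0.25 by default. The rule is the simplest monotone coupling of
  heteroatom contrast into the kernel width; it applies to both H₀ and H₁
  bars through their tagged edge pair, and λ = 0 recovers a plain
  persistence image exactly.
* **Invariances.** The descriptor depends on the distance matrix and the
  element multiset only, hence is invariant under translation, rotation,
  reflection and atom reordering; tests assert all of these.
* **Config hash.** Every image configuration hashes to a short digest
  stored with trained models; ranking refuses descriptor matrices whose
  hash disagrees, so train/predict featurization mismatches fail loudly.

## Surrogate

Laplacian-kernel ridge regression: K = exp(−γ·L1), dual coefficients from a
symmetric positive-definite solve of (K + αI)c = y (scipy; one 1e-10
diagonal jitter retry on failure, logged). Descriptors enter unscaled —
persistence images already share a common intensity scale. Model selection
is a full (α, γ) grid evaluation under seeded shuffled k-fold CV (k = 3
default; a 345-row dataset splits 230 train / 115 test per fold) followed
by the one-standard-error rule: among grid points whose mean test R² is
within sd(best)/√k of the best, pick the largest α, breaking ties toward
the smallest γ. "More regularized" is defined as larger α because γ's
complexity direction is kernel-dependent; the full score table is returned
for audit. Default grids are log-spaced, α ∈ [10⁻³, 10] and γ ∈ [10⁻⁴, 1]
with 25 points each; the grid search computes the pairwise L1 matrix once
and re-exponentiates per γ. R² on a zero-variance truth vector is reported
as NaN with an explicit `r2_defined=False` flag.

## Discovery loop

Candidates are ranked by predicted ΔH ascending (strongest predicted
binder first), ties broken by candidate id so reports are byte-reproducible
under a fixed seed. The validation draw is stratified on predicted ΔH with
boundaries (−5, −7) kcal·mol⁻¹ and counts (3, 3, 5) — weakest stratum
ΔH > −5, middle −7 ≤ ΔH ≤ −5, strongest ΔH < −7 — sampled uniformly without
replacement within each stratum; an understocked stratum raises an error
naming it. Augmentation unions the validated labels into the training set
(id collisions rejected), re-runs the grid search from scratch, and
preserves per-row provenance tags. An optional family filter restricts the
draw, off by default.

**Conformation classifier.** A least-squares plane is fitted through the
four bridge atoms; each aryl ring's orientation is the sign of
dot(para-axis, plane normal), where the para-axis runs from the midpoint of
the ring's two bridge-attached carbons to its para carbon. The cyclic sign
pattern maps to cone (4–0), partial cone (3–1), 1,2-alternate (adjacent
2–2) or 1,3-alternate (alternating 2–2); any ring whose axis cosine is
below 0.1 in magnitude yields `undetermined`. The para-axis was chosen over
the ring-plane normal as the orientation probe because the normal's
out-of-plane component vanishes exactly for rings standing perpendicular to
the bridge plane — the geometry the common cone conformer approaches —
whereas the para-axis is well conditioned there and degenerates precisely
in the flat (genuinely undetermined) case. The classifier needs an atom map
(ring membership and bridge indices); ring perception from raw coordinates
is out of scope, so maps come from the generator or from manifest metadata.

**Group summaries** use linear-interpolation (type-7) quartiles, whiskers
at the most extreme datum within 1.5×IQR of the box, and everything beyond
listed as outliers — the dominant box-plot convention, declared for
reproducibility.

## Enumeration

Substituent attachment follows a first-atom convention: the first atom of
the substituent SMILES bonds to the scaffold site by a single bond, so the
valency filter accepts a string iff that atom has ≥ 1 implicit/explicit
hydrogen to trade (RDKit accounting). `FC` fails (saturated fluorine);
bare `O` and `CO` are accepted but rewritten to explicit `[OH]` / `C[OH]`
so the attachment is an unambiguous single-bond hydroxyl / hydroxymethyl
rather than a double-bonded oxygen or carbonyl. Products are assembled
from per-family SMILES templates (bridge atom C/N/O/S; para, meta, lower
rim everywhere; bridge site only for C and N bridges, whose bridging atom
carries a substitutable hydrogen), all four symmetric positions carrying
the same group; lower-rim substitution replaces the phenolic hydrogen.
Products that fail SMILES round-trip parsing are retained with a `failed`
flag rather than silently dropped. Enumeration emits SMILES identities
only; 3D embedding belongs to external conformer/DFT tooling or to the
synthetic generator.

## Synthetic data

The fixtures module emulates the statistical shape of the real problem
without any quantum chemistry:

* **Geometries.** Four idealized benzene hexagons (1.40 Å sides) sit on the
  edges of a 5.0 Å bridge-atom square, tilted 45° out of the bridge plane
  with the sign pattern of the requested conformation; a lower-rim oxygen
  hangs off each ring and optional linear carbon chains extend from the
  para positions. Gaussian coordinate noise (default 0.02 Å) roughens the
  ideal geometry. These clouds exercise both image channels (hexagons
  guarantee H₁ mass), all four conformation labels and heteroatom edges —
  but they are *not* physical: no force field, no hydrogens, idealized
  planarity. Passing tests demonstrate algorithmic correctness and
  statistical recoverability, not chemical accuracy on DFT geometries.
* **Labels.** ΔH_i = w·PI(x_i) + b + ε with w supported on the 20
  highest-variance pixels, rescaled and centered so the noiseless labels
  have mean −5 and sd 2.5 kcal·mol⁻¹ (a realistic physisorption range
  spanning roughly −13 to 0), and ε ~ N(0, 0.3 kcal·mol⁻¹) — noise on the
  order of a converged DFT protocol's dispersion. The generator records the
  exact support, weights and intercept so recovery tests have ground truth.
* **Determinism.** Every generator consumes an explicit seed; identical
  seeds give bit-identical clouds and labels.

## Problem sizes and tolerances

The test suite and acceptance script run the recovery study at 300
structures with a 7×7 log-spaced hyperparameter grid, the oracle
equivalence at 100 random 5–12 atom clouds, the KRR/dense-solve comparison
at n = 50 (tolerance 1e-8 relative), and the discovery loop at 345 training
structures with a 150-candidate pool and two augmentation rounds (+11, +5).
These sizes keep a full run to tens of seconds while leaving every
statistical conclusion comfortably away from its threshold (recovery test
R² ≈ 0.98 against a 0.7 criterion).

## Known limitations

* Only H₀/H₁ are computed; no H₂, no alpha or Čech filtrations.
* The H₁ reduction is pure Python — fine for molecules (≲ 200 atoms at
  r_max 7 Å), not for large point clouds.
* The elemental-modulation functional form (multiplicative in |Δχ|) is a
  design choice exposed via λ, not a fitted quantity.
* The conformation classifier requires an externally supplied atom map and
  a clear ring tilt; near-flat geometries are deliberately classified
  `undetermined` rather than guessed.
* Real adsorption enthalpies are ensemble properties of flexible hosts;
  a single-geometry descriptor cannot capture conformer ensembles, and the
  synthetic label law is linear in pixel space by construction — real
  structure–enthalpy maps need not be.
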