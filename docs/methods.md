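# Methods

## The problem

The hydrodynamic radius R_h is the radius of the rigid sphere with the
same translational diffusion coefficient as the molecule
(R_h = k_B T / 6πηD). For intrinsically disordered proteins (IDPs) and
for multidomain proteins with flexible linkers, R_h is an ensemble
property: it must be computed as an average over conformations, and the
way folded domains are represented matters — treating a multidomain
protein as fully disordered systematically overestimates its size.

`idphydro` implements a minimal coarse-grained pipeline: build a
globule–linker bead chain from sequence plus disorder annotation,
sample its equilibrium ensemble as a self-avoiding random walk of
spheres, and evaluate R_h with bead-model hydrodynamics.

## Globule–linker model (GLM)

**Domain selection.** A residue run is ordered when its disorder
probability is strictly below 0.5 for at least 3 consecutive residues
(ties at 0.5 count as disordered). Disordered loops of at most 14
residues flanked by ordered segments on both sides are absorbed,
fusing the flanking segments into one folded domain; merging is
iterated left-to-right to a fixed point (a merge can create a new
flanking configuration). Terminal disordered tails are never absorbed.
Explicit domain intervals (TSV) bypass this stage entirely.

**Bead geometry.** Each folded domain becomes one sphere of radius

    R = (3 m / 4 π ρ)^(1/3) + a_hyd,

with ρ = 0.52 Da/Å³ (bulk density of folded protein) and a single
hydration layer a_hyd = 3 Å. The domain mass m is the sum of average
residue masses (monomer minus water) — average rather than
monoisotopic because ρ is a bulk average density, and no terminal
water because domains are interior to a chain. Ambiguity codes
X/B/Z/U map to the mean standard-residue mass (a strict mode raises
instead). Each disordered residue becomes one bead of steric diameter
3.8 Å, the canonical trans-peptide Cα–Cα spacing (exposed as a
parameter; the source model states the diameter equals the Cα–Cα
distance without fixing a number).

## Conformational sampling (SARWS)

The ensemble is the *self-avoiding random walk of spheres*: consecutive
bead centers are separated by exactly the sum of their steric radii,
bond directions are i.i.d. uniform on the sphere, and the distribution
is conditioned on no pair with |i−j| ≥ 2 coming closer than
(sᵢ+sⱼ)(1−ε). The relative tolerance ε = 1e−9 exists only to keep
exactly-touching configurations from being rejected by floating-point
rounding.

Sampling is exact recursive **dimerization**: split the bead list in
half, draw a valid SARWS for each half independently, join them with a
fresh uniform junction direction, and accept only if no inter-half
overlap occurs; on rejection BOTH halves and the junction direction are
redrawn. This reproduces the exact conditional distribution (the
classical dimerization argument for self-avoiding walks) and is far
faster than one-by-one growth with restarts. Chains of ≤ 8 beads are
sampled by one-shot rejection, with walks aborted at the first clash
during growth (equivalent to full-walk rejection, since an early clash
already decides the outcome).

Two implementation points that do not alter the distribution:

- *Surplus pooling.* Accepted half-segments are i.i.d. draws from their
  span's SARWS distribution, so surplus segments from one join attempt
  are kept in a per-span pool and consumed by later attempts within the
  same sampling run. Each segment is generated from fresh random numbers
  and used exactly once; pooling removes the multiplicative cost of
  discarding overshoot at every recursion level.
- *JIT kernels.* Short-walk generation and join overlap checks run in
  numba kernels with early exit; all randomness comes from the single
  seeded numpy Generator, so ensembles are bit-reproducible from
  (chain, n, seed).

A rejection budget of 10⁶ rounds per span raises a sampling-failure
error rather than hanging on pathological geometries.

## Hydrodynamic estimators

Before computing mobilities, disordered-residue beads are inflated to a
hydrodynamic radius of 4.2 Å (the median single-residue value); the
resulting overlaps between neighboring linker beads are intentional and
demand overlap-capable mobility expressions. R_h depends only weakly
(logarithmically) on this thickness.

**Kirkwood.** Full form: 1/R_h = N⁻²(Σᵢ 1/aᵢ + Σ_{i≠j} ⟨1/r_ij⟩);
the simplified form drops the single-bead terms (their contribution
vanishes in the large-N limit) and is the variant used for the
Kirkwood benchmark rows. Both use the bare inverse distance even for
overlapping beads, as the formulas are conventionally written; a flag
(`use_grpy_overlap`) substitutes the regularized pair trace for
sensitivity analysis. The full Kirkwood value is the short-time
diffusivity of the geometric center.

**Minimum dissipation approximation (MDA).** The trace-contracted,
viscosity-scaled generalized Rotne–Prager–Yamakawa (GRPY) pair
mobility is

    A_ij(r) = 1/r                                   r ≥ aᵢ+aⱼ
            = (aᵢ+aⱼ)/(2aᵢaⱼ) − ((aᵢ−aⱼ)² + r²)/(4aᵢaⱼ r)
                                                    |aᵢ−aⱼ| < r < aᵢ+aⱼ
            = 1/max(aᵢ,aⱼ)                          r ≤ |aᵢ−aⱼ|

(continuous at both boundaries; the far branch is 1/r because the
finite-size RPY corrections are traceless). The matrix
A_ij = 2πη Tr⟨μ_ij⟩ is averaged over the ensemble FIRST — the angle
brackets sit inside A — then inverted once: B = A⁻¹,
R_h = Σ_ij B_ij, diffusion-center weights xᵢ = Σⱼ B_ij / Σ_kj B_kj.
Equivalently 1/R_h minimizes xᵀAx over weights summing to one, which
is why R_h(MDA) ≥ R_h(Kirkwood, full) for every ensemble: uniform
weights are feasible, optimal ones are better. The inversion uses a
Cholesky factorization; a non-positive-definite A raises an error
naming the smallest eigenvalue rather than being silently regularized.

Viscosity and temperature never enter the R_h computation (η cancels
in A·B); they appear only in the Stokes–Einstein conversion to D.

**Uncertainty.** Per-conformer MDA values do not exist (one inversion
per ensemble), so the standard error is estimated by batch means: the
ensemble is split into 4 disjoint batches, A is rebuilt and inverted
per batch, and the SEM of the batch estimates is reported.

## Benchmark metrics

Six statistics compare predicted to measured radii: RMSD (Å), RMSRD
(%, relative to experiment), R², adjusted R², and the third quartiles
of absolute (Å) and relative (%) error. R² is the coefficient of
determination about the experimental mean — not a squared correlation —
so poor predictors score negative values; the adjustment
1 − (1−R²)(n−1)/(n−n_fp−1) charges each method its number of fitted
parameters (0 for the simulation methods, 1–2 for the power laws).
Quartiles use linear interpolation between order statistics
(configurable; the convention is otherwise arbitrary).

Power-law baselines R_h = R₀·N^γ are fitted by ordinary least squares
in log–log space (multiplicative errors match the relative-error
emphasis of RMSRD); the one-parameter variant pins γ at the Zimm value
0.588 (configurable — the exact convention for the one-parameter
"random coil" row is not pinned down by the source) and fits only R₀.
All fitted baselines are scored under leave-one-out cross-validation
so they are comparable with the zero-parameter simulation methods.

## Synthetic fixtures

The generator emits random sequences over the 20 standard residues
with block layouts of ordered/disordered segments; disorder
probabilities are centered at 0.1 (ordered) and 0.9 (disordered) with
uniform jitter capped at ±0.4 so no residue can cross the 0.5
threshold. It emulates the *format and structure* of real inputs —
sequence, consistent probability track, known domain masses — but not
the statistics of real proteins: no composition bias in linkers, no
correlated disorder scores, no experimental noise in R_h. A green test
on fixtures therefore establishes the pipeline's internal correctness,
not agreement with experiment; the experimental benchmark requires
user-supplied measured radii and real disorder predictions.

## Known limitations and numerical notes

- Linker beads carry no sequence-specific interactions (no
  electrostatics, no charge patterning); at physiological ionic
  strength screening justifies this, but strongly charged IDPs under
  low-salt conditions will be mispredicted.
- The effective scaling exponent of R_h versus N over N = 100–800 is
  ~0.55, below the asymptotic excluded-volume value 0.588: R_h carries
  strong finite-size corrections (additive thickness terms and
  slowly-decaying ⟨1/r⟩ contributions), so the asymptotic exponent is
  approached from below. The acceptance checks account for this with a
  finite-size tolerance.
- Degenerate inputs: single-bead chains return the bead radius for the
  full Kirkwood and MDA estimators; the simplified Kirkwood formula is
  undefined for one bead and raises.
- Sampling cost grows like N^~2.7 (constant per-level join acceptance
  ≈ 0.3 for touching hard spheres); N = 800 chains with hundreds of
  conformers take minutes on one core.
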