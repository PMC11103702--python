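# idphydro

Hydrodynamic radii of intrinsically disordered proteins (IDPs) from
coarse-grained globule–linker bead models.

Most proteins with disordered regions are neither compact globules nor
fully unstructured chains: folded domains are tethered by flexible
linkers, and the measurable quantity that summarizes their overall size
in solution — the hydrodynamic radius R_h from FCS, PFG-NMR, DLS, SEC
or AUC — depends on both. `idphydro` predicts R_h for such proteins
from nothing but the amino-acid sequence and a per-residue disorder
annotation (a DISOPRED3-style probability track, or explicit domain
intervals).

## Model

1. **Globule–linker model (GLM).** Residues with disorder probability
   P < 0.5 over at least 3 consecutive positions form ordered segments;
   disordered loops of ≤ 14 residues flanked by ordered segments are
   absorbed into a single folded domain. Each domain becomes one sphere
   of radius (3m / 4πρ)^(1/3) + a_hyd with ρ = 0.52 Da/Å³ and a
   hydration layer a_hyd = 3 Å; each disordered residue becomes one bead
   of steric diameter 3.8 Å (the Cα–Cα spacing).
2. **Conformational sampling (SARWS).** Bead centers follow a
   self-avoiding random walk of spheres: consecutive beads touch
   exactly, bond directions are uniform on the sphere, and the walk is
   conditioned on no non-adjacent steric overlap. Sampling uses exact
   recursive dimerization with vectorized/JIT-compiled rejection.
3. **Hydrodynamics.** Linker beads are inflated to a hydrodynamic
   radius of 4.2 Å, and R_h is computed from ensemble averages:
   - Kirkwood: 1/R_h = N⁻² (Σᵢ 1/aᵢ + Σ_{i≠j} ⟨1/r_ij⟩), with the
     simplified large-N form dropping the single-bead terms;
   - minimum dissipation approximation (MDA): A_ij = 2πη Tr⟨μ_ij⟩ from
     the generalized Rotne–Prager–Yamakawa mobility (closed forms for
     overlapping, polydisperse spheres), B = A⁻¹, R_h = Σ_ij B_ij, with
     diffusion-center weights xᵢ = Σⱼ B_ij / Σ_kj B_kj. The MDA is the
     tightest short-time upper bound on the long-time diffusivity and
     always satisfies R_h(MDA) ≥ R_h(Kirkwood, full).

Benchmark scoring (RMSD, RMSRD, coefficient-of-determination R² and its
parameter-adjusted form, third quartiles of absolute and relative
error) and leave-one-out power-law baselines R_h = R₀·N^γ are included.

## Worked example

```bash
python examples/predict_hydrodynamic_radius.py
```

prints (exact values are seed-reproducible):

```
protein length: 240 residues, 2 folded domains
R_h (MDA):                   33.42 +/- 0.17 A
R_h (Kirkwood, full):        23.32 A
R_h (Kirkwood, simplified):  24.79 A
D (Stokes-Einstein, water at 20 C): 6.411e-11 m^2/s
```

The MDA estimate exceeds the full Kirkwood value (it always does — the
diffusion-center weighting is optimal, the geometric-center weighting is
not), and the Stokes–Einstein line converts R_h to the translational
diffusion coefficient that FCS or PFG-NMR would measure in water at
20 °C. Other examples: `sample_conformers_xyz.py` (ensemble export),
`scaling_exponent.py` (excluded-volume scaling), `benchmark_metrics.py`
(error statistics against measured radii).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the excluded-volume scaling of the model:
mean MDA R_h for fully disordered chains of 100–800 residues
(200 conformers each) and the fitted log–log exponent, written as JSON.

## Layout

- `src/idphydro/bead_model.py` — sequence + disorder → bead chain
- `src/idphydro/sampler.py`, `_kernels.py` — SARWS ensemble sampling
- `src/idphydro/hydrodynamics.py` — Kirkwood, GRPY trace mobilities, MDA
- `src/idphydro/metrics.py` — error statistics, power-law baselines
- `src/idphydro/io.py` — FASTA / disorder-track / TSV / CSV / XYZ
- `src/idphydro/fixtures.py` — synthetic-protein generator
- `docs/methods.md` — model assumptions, parameters, numerical choices
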