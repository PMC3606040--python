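# solvscale

Fast analytical bulk-solvent and overall anisotropic scaling of
macromolecular crystallographic structure factors.

## The problem

Macromolecular crystals are 20–90% disordered solvent, and their diffracted
intensities are usually anisotropic. Before an atomic model can be compared
with observed amplitudes — in refinement, map calculation or validation —
both effects must be put into the total model structure factor

```
F_model = k_total (F_calc + k_mask F_mask),
k_total = k_overall · k_isotropic · k_anisotropic,
```

where **F**_calc comes from the atomic model, **F**_mask from the flat
(mask-based) bulk-solvent model, k_mask is the solvent scale and k_total
collects the overall, resolution-dependent and direction-dependent scales.
`solvscale` determines all of these scales analytically:

* **Per-bin solvent and isotropic scales.** With K = k_total⁻² the
  least-squares problem in each resolution bin reduces to a cubic equation
  in k_mask whose leading coefficient is non-negative by the Cauchy–Schwarz
  inequality; the admissible root with the smallest residual gives the bin's
  (K, k_mask) in closed form — no iterative search, no local minima.
* **Anisotropic scaling** by the exponential model
  k_aniso = exp(−2π² sᵗU_cryst s) with point-group symmetry constraints
  derived from first principles (solving RᵗUR = U), fitted analytically in
  the log domain; or by the 12-parameter polynomial model
  k_aniso = 1 + sᵗV₀s + s²·sᵗV₁s fitted on the amplitude residual; or by
  L-BFGS polish of the exponential model.
* **Logarithmic resolution binning** — bins uniform in ln(d) with a
  count floor, giving detailed low-resolution bins where the solvent signal
  varies fastest.
* **Twin fractions** for twinned data by a Lagrange-constrained linear
  system, alternated with scale determination.
* An **R-factor grid refinement** per bin, because the least-squares and
  R-factor minima can sit at different (k_mask, k_isotropic).

Intended users: methods developers and structural biologists who need a
transparent, tested, self-contained implementation of analytic scaling to
experiment with — not a replacement for a full refinement package.

## Worked example

```python
import numpy as np
from solvscale import ScalingModel, SimulationSpec, UnitCell, simulate
from solvscale.reflection_model import derive_constraint_matrix, point_group_rotations

# synthetic dataset with known truth: flat solvent (k_sol=0.35, B_sol=50),
# tetragonal anisotropy, 1% amplitude noise
c = derive_constraint_matrix(point_group_rotations("P 4/m m m"))
spec = SimulationSpec(
    cell=UnitCell(60, 60, 90), spacegroup="P 4/m m m",
    d_min=2.0, d_max=40.0, n_reflections=20000,
    k_sol=0.35, b_sol=50.0, u_cryst=c.rows.T @ np.array([3e-5, -2e-5]),
    noise=0.01, seed=7,
)
f_obs, f_calc, f_mask, refl, truth = simulate(spec)

result = ScalingModel(f_obs, f_calc, f_mask, refl).fit()
print(result.summary())
```

prints

```
Bulk-solvent and anisotropic scaling
====================================================
reflections:        20000
resolution range:   38.38 - 2.00 A
aniso method:       exp_anal
cycles:             3
k_overall:          0.943697
R(all):             0.0082
R(low, d>8A|500):   0.0094
R(high bin):        0.0088
k_sol, B_sol:       0.3211, 38.34 A^2
B_cart (11,22,33):  -6.52, -6.52, 16.67
per-cycle R: 0.01174, 0.00823, 0.00822
```

Reading this: the protocol converged in 3 cycles to an overall R factor of
0.0082 — consistent with the 1% noise floor — with good agreement also in
the low- and high-resolution subsets. The per-bin k_mask curve is
summarised by the best-fitting classical exponential (k_sol, B_sol); it is
close to, but not exactly, the generating values because the per-bin curve
is free-form and the R-factor grid refinement optimises R rather than the
solvent parameters themselves. The anisotropic tensor is reported as
Cartesian B values (truth here: −4.0, −4.0, +19.2 Å²; part of the isotropic
component of the tensor is absorbed by the binned isotropic scale, which is
expected — only the product k_total is constrained by the data).

`result.bin_table()` gives the per-bin breakdown (resolution range, count,
K, raw and smoothed k_mask, R per bin); `solvscale --help` exposes the same
pipeline as a command line for MTZ / mmCIF / TSV reflection files.

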