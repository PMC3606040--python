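"""Synthetic reflection data with known ground truth for every scaling stage.

The generator emulates the forward model the scaling protocol inverts:
complex F_calc and F_mask are drawn as circular Gaussians with exponential
resolution falloff (the mask component decaying much faster, so solvent
dominates at low resolution), and observed amplitudes are composed as

    F_obs = k_total(s) · |F_calc + k_mask(s²) · F_mask| · (1 + noise),

with k_total = k_overall · k_isotropic(s²) · k_anisotropic(s) and a flat
solvent curve k_mask = k_sol·exp(−B_sol·s²/4) (or any explicit curve).
Under twinning F_obs = [Σ_j α_j I_j]^(1/2)·(1 + noise). Everything is
reproducible from the integer seed, and the returned ground-truth record
suffices to rebuild F_obs bit-exactly from F_calc and F_mask.

Defaults are chosen to mimic a typical mid-resolution protein dataset:
falloff B of 20 Å² for the model and 150 Å² for the mask contribution,
solvent parameters around k_sol ≈ 0.35, B_sol ≈ 46 Å², and relative
Gaussian amplitude noise of ~1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reflection_model import ReflectionSet, UnitCell, point_group_rotations
from .aniso import k_aniso_exponential, k_aniso_polynomial

__all__ = ["SimulationSpec", "simulate", "babinet_stress_case", "lattice_indices"]


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic dataset."""

    cell: UnitCell = field(default_factory=lambda: UnitCell(60.0, 70.0, 80.0))
    spacegroup: str = "P 1"
    d_min: float = 2.0
    d_max: float = 30.0
    n_reflections: int = 10000
    k_sol: float = 0.35
    b_sol: float = 46.0
    k_mask_curve: object = None  # optional callable s2 -> k_mask, overrides (k_sol, b_sol)
    u_cryst: np.ndarray | None = None  # exponential aniso truth (6-vector)
    v0: np.ndarray | None = None  # polynomial aniso truth
    v1: np.ndarray | None = None
    k_overall: float = 1.0
    b_isotropic: float = 0.0  # k_isotropic = exp(-B s²/4)
    b_model: float = 20.0  # |F_calc| falloff
    b_mask: float = 150.0  # |F_mask| falloff
    twin_operators: np.ndarray | None = None
    twin_fractions: np.ndarray | None = None
    noise: float = 0.0  # relative Gaussian sigma on amplitudes
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError("need 0 < d_min < d_max")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.twin_fractions is not None:
            fr = np.asarray(self.twin_fractions, float)
            if abs(fr.sum() - 1.0) > 1e-9:
                raise ValueError("twin fractions must sum to 1")

    def k_mask_of(self, s2: np.ndarray) -> np.ndarray:
        if self.k_mask_curve is not None:
            return np.asarray(self.k_mask_curve(s2), float)
        return self.k_sol * np.exp(-self.b_sol * s2 / 4.0)


def lattice_indices(
    cell: UnitCell, d_min: float, d_max: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """All lattice points with d in [d_min, d_max], one hemisphere (no
    Friedel duplicates, (0,0,0) excluded)."""
    from .reflection_model import reciprocal_metric_tensor, s_squared

    g = reciprocal_metric_tensor(cell)
    hmax = int(np.ceil(d_min**-1 * cell.a)) + 1
    kmax = int(np.ceil(d_min**-1 * cell.b)) + 1
    lmax = int(np.ceil(d_min**-1 * cell.c)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(0, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    # hemisphere: l > 0, or l == 0 and (k > 0 or (k == 0 and h > 0))
    hemi = (hkl[:, 2] > 0) | (
        (hkl[:, 2] == 0) & ((hkl[:, 1] > 0) | ((hkl[:, 1] == 0) & (hkl[:, 0] > 0)))
    )
    hkl = hkl[hemi]
    s2 = s_squared(hkl, g)
    d = 1.0 / np.sqrt(s2)
    return hkl[(d >= d_min) & (d <= d_max)]


def simulate(spec: SimulationSpec):
    """Generate (f_obs, f_calc, f_mask, reflections, truth) from a spec.

    ``truth`` is a dict holding every per-reflection scale used in the
    forward composition, so F_obs can be reconstructed bit-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    hkl = lattice_indices(spec.cell, spec.d_min, spec.d_max)
    if len(hkl) < spec.n_reflections:
        raise ValueError(
            f"lattice holds only {len(hkl)} reflections in "
            f"[{spec.d_min}, {spec.d_max}] A; requested {spec.n_reflections}"
        )
    if spec.twin_operators is not None:
        hkl = _close_under_operators(hkl, np.asarray(spec.twin_operators, int))
    pick = rng.choice(len(hkl), size=min(spec.n_reflections, len(hkl)), replace=False)
    hkl = hkl[np.sort(pick)]
    if spec.twin_operators is not None:
        hkl = _close_under_operators(hkl, np.asarray(spec.twin_operators, int))
    refl = ReflectionSet.from_symbol(hkl, spec.cell, spec.spacegroup)
    n = len(refl)
    s2 = refl.s_squared

    env_calc = np.exp(-spec.b_model * s2 / 4.0)
    env_mask = np.exp(-spec.b_mask * s2 / 4.0)
    f_calc = env_calc * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    f_mask = env_mask * (rng.standard_normal(n) + 1j * rng.standard_normal(n))

    k_mask = spec.k_mask_of(s2)
    k_iso = np.exp(-spec.b_isotropic * s2 / 4.0)
    if spec.u_cryst is not None:
        k_aniso = k_aniso_exponential(spec.u_cryst, refl.indices)
    elif spec.v0 is not None:
        k_aniso = k_aniso_polynomial(spec.v0, spec.v1, refl)
    else:
        k_aniso = np.ones(n)
    k_total = spec.k_overall * k_iso * k_aniso

    if spec.twin_operators is not None:
        fr = np.asarray(spec.twin_fractions, float)
        ops = np.asarray(spec.twin_operators, int)
        rows = _mate_rows(refl.indices, ops)
        i_total = np.zeros(n)
        for j in range(len(ops)):
            amp_j = np.abs(f_calc[rows[j]] + k_mask[rows[j]] * f_mask[rows[j]])
            i_total += fr[j] * (k_total[rows[j]] * amp_j) ** 2
        clean = np.sqrt(i_total)
    else:
        clean = k_total * np.abs(f_calc + k_mask * f_mask)

    noise_mult = 1.0 + spec.noise * rng.standard_normal(n) if spec.noise else np.ones(n)
    if spec.outlier_fraction > 0:
        hit = rng.random(n) < spec.outlier_fraction
        noise_mult = np.where(
            hit, noise_mult * spec.outlier_scale ** rng.standard_normal(n), noise_mult
        )
    f_obs = np.maximum(clean * noise_mult, 0.0)

    truth = {
        "k_mask": k_mask,
        "k_isotropic": k_iso,
        "k_anisotropic": k_aniso,
        "k_total": k_total,
        "noise_mult": noise_mult,
        "f_obs_clean": clean,
        "spec": spec,
    }
    return f_obs, f_calc, f_mask, refl, truth


def _close_under_operators(hkl: np.ndarray, ops: np.ndarray) -> np.ndarray:
    """Extend an index set so every twin mate (up to Friedel) is present."""
    have = {tuple(x) for x in hkl}
    have |= {tuple(-x) for x in hkl}
    out = [tuple(x) for x in hkl]
    for t in ops:
        for x in hkl:
            m = tuple(t @ x)
            if m not in have and tuple(-np.array(m)) not in have:
                have.add(m)
                out.append(m)
    return np.array(sorted(set(out)))


def _mate_rows(indices: np.ndarray, ops: np.ndarray) -> np.ndarray:
    lookup = {}
    for row, x in enumerate(indices):
        lookup[tuple(x)] = row
        lookup.setdefault(tuple(-x), row)
    rows = np.zeros((len(ops), len(indices)), dtype=int)
    for j, t in enumerate(ops):
        for i, x in enumerate(indices):
            rows[j, i] = lookup[tuple(t @ x)]
    return rows


def babinet_stress_case(spec: SimulationSpec, p: float = 0.9):
    """Low-resolution data built with F_mask = −p·F_calc exactly.

    In this regime the solvent term is anticorrelated with the model term,
    so F_model = k_total(1 − p·k_mask)·F_calc: any two scale pairs with
    equal k_total(1 − p·k_mask) give identical model amplitudes, and the
    (k_total, k_mask) decomposition is degenerate.
    """
    f_obs, f_calc, _, refl, truth = simulate(spec)
    f_mask = -p * f_calc
    k_mask = truth["k_mask"]
    clean = truth["k_total"] * np.abs(f_calc + k_mask * f_mask)
    f_obs = np.maximum(clean * truth["noise_mult"], 0.0)
    truth = dict(truth, f_obs_clean=clean, babinet_p=p)
    return f_obs, f_calc, f_mask, refl, truth
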