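"""Twin-fraction estimation and scaling in the presence of twinning.

A twinned crystal with N orientation domains produces observed intensities
that are mixtures of the model intensities of twin-related reflections,

    I_model(s) = Σ_j α_j I_j(s),    I_j(s) = k_total² |F_calc(T_j s) + k_mask F_mask(T_j s)|²,

with twin fractions α_j ≥ 0, Σ α_j = 1, and integer twin operators T_j
acting on Miller indices (T_1 = identity). k_total and k_mask are assumed
identical across domains. The fractions minimising
Σ_s (I_obs(s) − Σ_j α_j I_j(s))² subject to Σ α_j = 1 solve, via a Lagrange
multiplier λ, the (N+1)×(N+1) linear system

    [ A   c·1 ] [α]   [b]        A_ij = Σ_s I_i I_j,  b_i = Σ_s I_obs I_i,
    [ 1ᵗ   0  ] [λ] = [1]

where the conditioning constant c = mean_s Σ_j I_j² keeps λ on the same
numerical scale as the fractions. Scale determination then reuses the
per-bin cubic with the α-weighted moments ū = Σ_j α_j u_j (and likewise
v̄, w̄) in place of (u, v, w); at N = 1 every formula reduces bit-for-bit
to the untwinned path. Fractions and scales are alternated to convergence;
a fraction escaping [0, 1] suspends its operator for the current iteration
only, the reduced system is re-solved, and the full set is tried again at
the next iteration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from . import binning, solvent
from .solvent import BinMoments

logger = logging.getLogger(__name__)

__all__ = [
    "TwinModel",
    "TwinIntensities",
    "parse_twin_operator",
    "twin_total_intensity",
    "estimate_twin_fractions",
    "solve_twin_bin_scales",
    "iterate_twin_scaling",
]


@dataclass
class TwinModel:
    """Twin operators (first = identity), estimated fractions and the
    Lagrange multiplier of the constrained fit."""

    operators: np.ndarray  # (N, 3, 3) int
    fractions: np.ndarray = None
    lagrange: float = 0.0

    def __post_init__(self) -> None:
        self.operators = np.asarray(self.operators, dtype=int)
        if self.fractions is None:
            n = len(self.operators)
            self.fractions = np.full(n, 1.0 / n)


@dataclass
class TwinIntensities:
    """Per-domain model intensities I_j(s) (rows = domains) and observed
    intensities I(s) = F_obs²."""

    i_model: np.ndarray  # (N, n_reflections)
    i_obs: np.ndarray


_AXIS = {"h": 0, "k": 1, "l": 2}


def parse_twin_operator(text: str) -> np.ndarray:
    """Parse a twin law written as a Miller-index triplet, e.g. '-h,-k,l'
    or 'k,h,-l', into a 3×3 integer matrix acting on (h,k,l) columns."""
    parts = [p.strip().lower() for p in text.split(",")]
    if len(parts) != 3:
        raise ValueError(f"twin law must have three components: {text!r}")
    mat = np.zeros((3, 3), dtype=int)
    term = re.compile(r"([+-]?\d*)\s*([hkl])")
    for row, part in enumerate(parts):
        consumed = 0
        for m in term.finditer(part):
            coef = m.group(1)
            coef = int(coef + "1") if coef in ("", "+", "-") else int(coef)
            mat[row, _AXIS[m.group(2)]] += coef
            consumed += len(m.group(0))
        if not part or not term.search(part):
            raise ValueError(f"cannot parse twin-law component {part!r}")
    return mat


def twin_total_intensity(model: TwinModel, intensities: TwinIntensities) -> np.ndarray:
    """Mixture intensity Σ_j α_j I_j(s) per reflection."""
    return model.fractions @ intensities.i_model


def estimate_twin_fractions(
    intensities: TwinIntensities, operators: np.ndarray | None = None
) -> TwinModel:
    """Solve the Lagrange-constrained linear system for the twin fractions.

    Σ α_j = 1 holds exactly in the solution; a near-singular system (e.g.
    indistinguishable domains) is solved in the least-squares sense with a
    warning.
    """
    i_model = np.asarray(intensities.i_model, float)
    i_obs = np.asarray(intensities.i_obs, float)
    n = i_model.shape[0]
    if operators is None:
        operators = np.array([np.eye(3, dtype=int)] * n)
    if n == 1:
        return TwinModel(operators, fractions=np.array([1.0]))
    a = i_model @ i_model.T
    b = i_model @ i_obs
    cond_const = float(np.mean(np.sum(i_model**2, axis=0)))
    if cond_const == 0.0:
        cond_const = 1.0
    sys = np.zeros((n + 1, n + 1))
    sys[:n, :n] = a
    sys[:n, n] = cond_const
    sys[n, :n] = 1.0
    rhs = np.concatenate([b, [1.0]])
    cond = np.linalg.cond(sys)
    if not np.isfinite(cond) or cond > 1e12:
        logger.warning("near-singular twin-fraction system (cond=%.3g); "
                       "using regularized least-squares solve", cond)
        sol, *_ = np.linalg.lstsq(sys, rhs, rcond=1e-10)
    else:
        sol = np.linalg.solve(sys, rhs)
    frac = sol[:n]
    # enforce the constraint exactly against round-off
    frac = frac - (frac.sum() - 1.0) / n
    return TwinModel(operators, fractions=frac, lagrange=float(sol[n]))


def _alpha_weighted_moments(
    moments: list[BinMoments], fractions: np.ndarray
) -> BinMoments:
    """ū = Σ_j α_j u_j etc.; the twinned normal equations have exactly the
    untwinned form in these averaged moments."""
    if len(moments) == 1 and fractions[0] == 1.0:
        return moments[0]  # bitwise reduction at N = 1
    u = sum(a * m.u for a, m in zip(fractions, moments))
    v = sum(a * m.v for a, m in zip(fractions, moments))
    w = sum(a * m.w for a, m in zip(fractions, moments))
    return BinMoments(u=u, v=v, w=w, i_obs=moments[0].i_obs)


def solve_twin_bin_scales(
    moments: list[BinMoments], fractions: np.ndarray
) -> tuple[float, float, dict]:
    """Per-bin (K, k_mask) under twinning: the untwinned cubic applied to
    the α-weighted moments. Identical to solve_bin_scales when N = 1."""
    return solvent.solve_bin_scales(_alpha_weighted_moments(moments, np.asarray(fractions, float)))


def _twin_mate_rows(indices: np.ndarray, operators: np.ndarray,
                    rotations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row index of each reflection's twin mate per domain.

    T_j s is looked up in the dataset after mapping through the point-group
    rotations and the Friedel inversion. Returns (rows (N, n), resolvable
    mask (n,)); unresolvable entries hold row 0 and mask False.
    """
    lookup = {}
    for row, hkl in enumerate(indices):
        for r in rotations:
            for sgn in (1, -1):
                lookup.setdefault(tuple(sgn * (r @ hkl)), row)
    n = len(indices)
    rows = np.zeros((len(operators), n), dtype=int)
    ok = np.ones(n, dtype=bool)
    for j, t in enumerate(operators):
        mapped = indices @ t.T
        for i, hkl in enumerate(mapped):
            row = lookup.get(tuple(hkl))
            if row is None:
                ok[i] = False
            else:
                rows[j, i] = row
    return rows, ok


def iterate_twin_scaling(
    f_obs: np.ndarray,
    f_calc: np.ndarray,
    f_mask: np.ndarray,
    reflections,
    operators: np.ndarray,
    min_count: int = binning.DEFAULT_MIN_COUNT,
    max_bins: int = binning.DEFAULT_MAX_BINS,
    max_iter: int = 10,
    r_tol: float = 1e-4,
) -> tuple[TwinModel, solvent.SolventScales]:
    """Alternate twin-fraction estimation with per-bin scale determination.

    Convergence is declared when the twinned R factor changes by less than
    ``r_tol`` (absolute) between iterations. Fractions leaving [0, 1] have
    their operators suspended for the current iteration (the reduced system
    is re-solved); the full operator set is retried on the next iteration.
    With a single (identity) operator the computation reduces exactly to
    the untwinned per-bin scaling.
    """
    operators = np.asarray(operators, dtype=int)
    n_dom = len(operators)
    f_obs = np.asarray(f_obs, float)
    f_calc = np.asarray(f_calc, complex)
    f_mask = np.asarray(f_mask, complex)

    rows, resolvable = _twin_mate_rows(
        reflections.indices, operators, reflections.rotations
    )
    if not resolvable.all():
        logger.info("%d reflections lack a resolvable twin mate; excluded "
                    "from fraction estimation", int((~resolvable).sum()))

    part = binning.log_d_bins(reflections.d, min_count=min_count, max_bins=max_bins)
    centers = part.centers_s2()
    s2 = reflections.s_squared

    # per-domain moments per bin
    dom_moments = []
    for j in range(n_dom):
        fc = f_calc[rows[j]]
        fm = f_mask[rows[j]]
        dom_moments.append(solvent.bin_moments(fc, fm, f_obs))

    model = TwinModel(operators)
    scales = None
    k_mask_refl = np.zeros_like(f_obs)
    k_total_refl = np.ones_like(f_obs)
    prev_r = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # --- fraction estimation at current scales ---
        i_model = np.empty((n_dom, len(f_obs)))
        for j in range(n_dom):
            amp = np.abs(f_calc[rows[j]] + k_mask_refl * f_mask[rows[j]])
            i_model[j] = (k_total_refl * amp) ** 2
        ti = TwinIntensities(i_model=i_model[:, resolvable],
                             i_obs=f_obs[resolvable] ** 2)
        active = np.ones(n_dom, dtype=bool)
        while True:
            sub = estimate_twin_fractions(
                TwinIntensities(ti.i_model[active], ti.i_obs), operators[active]
            )
            frac = np.zeros(n_dom)
            frac[active] = sub.fractions
            bad = active & ((frac < 0.0) | (frac > 1.0))
            if not bad.any() or active.sum() <= 1:
                break
            active &= ~bad  # suspend for this iteration only
        if not active.any() or frac[0] == 0.0 and active.sum() == 0:
            logger.warning("no admissible twin fractions; untwinned fallback")
            frac = np.zeros(n_dom)
            frac[0] = 1.0
        model = TwinModel(operators, fractions=np.clip(frac, 0.0, 1.0),
                          lagrange=sub.lagrange)

        # --- per-bin scales at current fractions ---
        nb = part.n_bins
        k_mask_bins = np.zeros(nb)
        k_total_bins = np.ones(nb)
        for b in range(nb):
            sel = part.bin_of == b
            bm = [BinMoments(m.u[sel], m.v[sel], m.w[sel], m.i_obs[sel])
                  for m in dom_moments]
            k_big, km, _ = solve_twin_bin_scales(bm, model.fractions)
            k_mask_bins[b] = km
            k_total_bins[b] = k_big ** -0.5
        k_mask_sm = solvent.smooth_kmask(k_mask_bins)
        k_mask_refl = solvent.interpolate_scales(k_mask_sm, centers, s2)
        k_total_refl = solvent.interpolate_scales(k_total_bins, centers, s2)

        # --- twinned R factor ---
        for j in range(n_dom):
            amp = np.abs(f_calc[rows[j]] + k_mask_refl * f_mask[rows[j]])
            i_model[j] = (k_total_refl * amp) ** 2
        f_model = np.sqrt(model.fractions @ i_model)
        r = float(np.abs(f_obs - f_model).sum() / f_obs.sum())
        if prev_r is not None and abs(prev_r - r) < r_tol:
            prev_r = r
            break
        prev_r = r

    scales = solvent.SolventScales(
        k_mask_bins=k_mask_bins,
        k_mask_bins_smoothed=k_mask_sm,
        k_total_bins=k_total_bins,
        k_isotropic_bins=k_total_bins.copy(),
        bin_centers_s2=centers,
        k_mask=k_mask_refl,
        k_isotropic=k_total_refl.copy(),
        notes=[f"twinned scaling: {n_iter} iterations, R={prev_r:.6f}"],
    )
    return model, scales
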