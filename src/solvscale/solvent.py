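"""Per-bin analytic bulk-solvent and isotropic scaling.

Within one resolution bin, with K = k_total⁻² held common to the bin, the
flat-mask model |F_model|² = k_total²·|F_calc + k_mask·F_mask|² is fitted in
intensity space by minimising

    LS(K, k_mask) = Σ_bin [ K·I − (u + 2 v k_mask + w k_mask²) ]²,

where I = F_obs², u = |F_calc|², w = |F_mask|² and v = Re⟨F_calc, F_mask⟩.
Setting both partial derivatives to zero and eliminating K yields a cubic
in k_mask whose leading coefficient ΣI²·Σw² − (ΣIw)² is non-negative by the
Cauchy–Schwarz inequality, so the stationary points are obtained in closed
form: among the real roots with k_mask ≥ 0 and K > 0 (plus the k_mask = 0
boundary), the one with the smallest LS is selected; K follows from the
first normal equation

    K = [Σ I u + 2 k_mask Σ I v + k_mask² Σ I w] / Σ I².

The per-bin k_mask curve is smoothed (Savitzky–Golay) without disturbing a
monotone trend, interpolated linearly in s² to individual reflections, and
optionally refined per bin by a grid search on the R factor, whose minimum
can sit away from the least-squares minimum. Classical two-parameter forms
k_sol·exp(−B_sol·s²/4) can be fitted to the per-bin curves for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

__all__ = [
    "BinMoments",
    "SolventScales",
    "bin_moments",
    "solve_bin_scales",
    "smooth_kmask",
    "interpolate_scales",
    "update_kisotropic",
    "fit_ksol_bsol",
    "fit_koverall_boverall",
    "rfactor_grid_refine",
    "ls_bin_residual",
]


@dataclass
class BinMoments:
    """Quadratic per-reflection moments of one bin, in squared-amplitude
    units: u = |F_calc|², v = Re⟨F_calc, F_mask⟩, w = |F_mask|², I = F_obs²."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    i_obs: np.ndarray


@dataclass
class SolventScales:
    """Per-bin solvent/isotropic scales and their per-reflection spreads."""

    k_mask_bins: np.ndarray
    k_mask_bins_smoothed: np.ndarray
    k_total_bins: np.ndarray  # k_total = K^(-1/2) per bin (aniso excluded)
    k_isotropic_bins: np.ndarray
    bin_centers_s2: np.ndarray
    k_mask: np.ndarray = None  # per reflection
    k_isotropic: np.ndarray = None  # per reflection
    k_sol: float | None = None
    b_sol: float | None = None
    k_overall: float | None = None
    b_overall: float | None = None
    n_excluded: int = 0
    notes: list = field(default_factory=list)


def bin_moments(
    f_calc: np.ndarray, f_mask: np.ndarray, f_obs: np.ndarray
) -> BinMoments:
    """Quadratic moments; v is the real inner product of the two complex
    structure factors, so |F_calc + x·F_mask|² = u + 2xv + x²w."""
    f_calc = np.asarray(f_calc, complex)
    f_mask = np.asarray(f_mask, complex)
    f_obs = np.asarray(f_obs, float)
    return BinMoments(
        u=np.abs(f_calc) ** 2,
        v=(f_calc * f_mask.conj()).real,
        w=np.abs(f_mask) ** 2,
        i_obs=f_obs**2,
    )


def ls_bin_residual(m: BinMoments, k_total_inv_sq: float, k_mask: float) -> float:
    """LS(K, k_mask) of one bin."""
    model = m.u + 2.0 * k_mask * m.v + k_mask**2 * m.w
    r = k_total_inv_sq * m.i_obs - model
    return float(r @ r)


class UndefinedScaleError(ValueError):
    """All observed intensities in the bin are zero; K is undefined."""


def _k_from_kmask(m: BinMoments, k_mask: float, d: float) -> float:
    """First normal equation: K as a function of k_mask."""
    a0 = float(m.i_obs @ m.u)
    a1 = float(m.i_obs @ m.v)
    a2 = float(m.i_obs @ m.w)
    return (a0 + 2.0 * k_mask * a1 + k_mask**2 * a2) / d


def cubic_coefficients(m: BinMoments) -> np.ndarray:
    """Coefficients (c3, c2, c1, c0) of the stationary-point cubic in k_mask.

    Derived by eliminating K between the two normal equations of LS; the
    leading coefficient c3 = ΣI²·Σw² − (ΣIw)² ≥ 0 (Cauchy–Schwarz).
    """
    i, u, v, w = m.i_obs, m.u, m.v, m.w
    d = float(i @ i)
    a0, a1, a2 = float(i @ u), float(i @ v), float(i @ w)
    c0 = float(u @ v)
    c1 = float(2.0 * (v @ v) + u @ w)
    c2 = 3.0 * float(v @ w)
    c3 = float(w @ w)
    return np.array(
        [
            d * c3 - a2 * a2,
            d * c2 - 3.0 * a1 * a2,
            d * c1 - a0 * a2 - 2.0 * a1 * a1,
            d * c0 - a0 * a1,
        ]
    )


def _real_roots(coeffs: np.ndarray) -> np.ndarray:
    """Real roots of a cubic given (c3, c2, c1, c0); degrades gracefully to
    quadratic/linear when the leading coefficients vanish. Roots are taken
    from the eigenvalues of the companion matrix (via numpy.roots), which is
    robust near-degeneracy."""
    c = np.asarray(coeffs, float)
    scale = np.max(np.abs(c))
    if scale == 0.0:
        return np.array([])
    c = c / scale
    lead = np.flatnonzero(np.abs(c) > 1e-12)
    if lead.size == 0:
        return np.array([])
    c = c[lead[0]:]
    if c.size == 1:
        return np.array([])
    roots = np.roots(c)
    return roots[np.abs(roots.imag) < 1e-8 * (1.0 + np.abs(roots.real))].real


def solve_bin_scales(m: BinMoments) -> tuple[float, float, dict]:
    """Analytic (K, k_mask) of one bin with the admissibility policy.

    Candidates are the real cubic roots with k_mask ≥ 0 whose induced K is
    positive, plus always the boundary k_mask = 0; the candidate with the
    smallest LS wins. Returns (K, k_mask, diagnostics).
    """
    d = float(m.i_obs @ m.i_obs)
    if d == 0.0:
        raise UndefinedScaleError("all observed intensities in bin are zero")
    coeffs = cubic_coefficients(m)
    roots = _real_roots(coeffs)
    candidates = [0.0] + [float(r) for r in roots if r >= 0.0]
    best = None
    rejected = 0
    for k_mask in candidates:
        k_big = _k_from_kmask(m, k_mask, d)
        if k_big <= 0.0:
            rejected += 1
            continue
        ls = ls_bin_residual(m, k_big, k_mask)
        if best is None or ls < best[2]:
            best = (k_big, k_mask, ls)
    if best is None:
        # K from the pure-model normal equation can only be non-positive if
        # Σ I·u <= 0, i.e. the bin carries no usable model signal.
        raise UndefinedScaleError("no admissible (K, k_mask) in bin")
    diagnostics = {
        "n_roots": int(roots.size),
        "n_rejected": rejected,
        "ls": best[2],
        "cubic_lead": float(coeffs[0]),
    }
    return best[0], best[1], diagnostics


def _is_monotone(x: np.ndarray) -> bool:
    dx = np.diff(x)
    return bool(np.all(dx >= 0) or np.all(dx <= 0))


def smooth_kmask(k_mask_bins: np.ndarray, window: int = 5, order: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing of the per-bin k_mask curve.

    Already-monotone input is returned unchanged (smoothing must not alter
    a monotone trend); negative filtered values are clamped to zero. The
    window shrinks for short inputs.
    """
    x = np.asarray(k_mask_bins, float)
    if x.size <= 2 or _is_monotone(x):
        return x.copy()
    win = min(window, x.size if x.size % 2 == 1 else x.size - 1)
    if win <= order:
        return x.copy()
    out = savgol_filter(x, window_length=win, polyorder=order, mode="interp")
    return np.maximum(out, 0.0)


def interpolate_scales(
    per_bin: np.ndarray, bin_centers_s2: np.ndarray, s2: np.ndarray
) -> np.ndarray:
    """Piecewise-linear interpolation of per-bin values in s², constant
    beyond the outer bin centers; a single bin yields a constant."""
    per_bin = np.asarray(per_bin, float)
    centers = np.asarray(bin_centers_s2, float)
    if per_bin.size == 1:
        return np.full(np.asarray(s2).shape, per_bin[0])
    order = np.argsort(centers)
    return np.interp(s2, centers[order], per_bin[order])


def update_kisotropic(f_obs: np.ndarray, model_amplitudes: np.ndarray) -> float:
    """Optimal per-bin scalar Σ(F_obs·|F′|)/Σ|F′|², the exact least-squares
    minimiser of Σ(F_obs − k·|F′|)² for the bin."""
    a = np.asarray(model_amplitudes, float)
    denom = float(a @ a)
    if denom == 0.0:
        raise ZeroDivisionError("bin model amplitudes are all zero")
    return float(np.asarray(f_obs, float) @ a) / denom


def _fit_exponential_curve(
    values: np.ndarray, s2: np.ndarray
) -> tuple[float, float] | None:
    """Fit k·exp(−B·s²/4) to (s², value) pairs with value > 0.

    Log-linearised weighted least squares (weights value²) in closed form,
    then a Levenberg–Marquardt polish on the untransformed residual.
    Returns None when fewer than two positive values remain.
    """
    y = np.asarray(values, float)
    x = np.asarray(s2, float)
    pos = y > 0
    if int(pos.sum()) < 2:
        return None
    y, x = y[pos], x[pos]
    # weighted linear fit of ln y = ln k − B x/4
    wgt = y**2
    a_mat = np.column_stack([np.ones_like(x), -x / 4.0])
    sol, *_ = np.linalg.lstsq(
        a_mat * wgt[:, None] ** 0.5, np.log(y) * wgt**0.5, rcond=None
    )
    log_k0, b0 = float(sol[0]), float(sol[1])

    def resid(p):
        return np.exp(p[0]) * np.exp(-p[1] * x / 4.0) - y

    fit = least_squares(resid, x0=[log_k0, b0], method="lm")
    k = float(np.exp(fit.x[0]))
    return (k, float(fit.x[1]))


def fit_ksol_bsol(
    k_mask_bins: np.ndarray, bin_centers_s2: np.ndarray
) -> tuple[float, float] | None:
    """Classical flat-model parameters (k_sol, B_sol) fitted to the per-bin
    k_mask curve over bins with k_mask > 0; None if fewer than two such
    bins (absence of a solvent model)."""
    return _fit_exponential_curve(k_mask_bins, bin_centers_s2)


def fit_koverall_boverall(
    k_bins: np.ndarray, bin_centers_s2: np.ndarray
) -> tuple[float, float] | None:
    """(k_overall, B_overall) of k_overall·exp(−B_overall·s²/4) fitted to
    the per-bin K (or k_total) curve; same rules as fit_ksol_bsol."""
    return _fit_exponential_curve(k_bins, bin_centers_s2)


def rfactor_grid_refine(
    f_obs: np.ndarray,
    f_calc: np.ndarray,
    f_mask: np.ndarray,
    k_mask_ls: float,
    k_iso_ls: float | None = None,
    n_steps: int = 41,
) -> tuple[float, float]:
    """Grid search for the (k_mask, k_isotropic) pair of one bin minimising
    the R factor, around the least-squares optimum.

    k_mask is scanned over [0, 2·k_mask_LS] ([0, 1] when the LS value is
    zero) in ``n_steps`` values; at each trial k_isotropic is re-derived as
    the optimal bin scalar. The LS pair itself is always a candidate, so
    the result is never worse in R.
    """
    f_obs = np.asarray(f_obs, float)
    f_calc = np.asarray(f_calc, complex)
    f_mask = np.asarray(f_mask, complex)
    hi = 2.0 * k_mask_ls if k_mask_ls > 0 else 1.0
    if n_steps <= 1:
        trials = np.array([k_mask_ls])
    else:
        trials = np.append(np.linspace(0.0, hi, n_steps), k_mask_ls)
    sum_fobs = float(f_obs.sum())
    if sum_fobs == 0.0:
        raise UndefinedScaleError("grid refinement needs nonzero F_obs")

    def r_of(km: float, kiso: float) -> float:
        amp = np.abs(f_calc + km * f_mask)
        return float(np.abs(f_obs - kiso * amp).sum()) / sum_fobs

    best = None
    if k_iso_ls is not None:
        best = (float(k_mask_ls), float(k_iso_ls), r_of(k_mask_ls, k_iso_ls))
    for km in trials:
        amp = np.abs(f_calc + km * f_mask)
        denom = float(amp @ amp)
        if denom == 0.0:
            continue
        kiso = float(f_obs @ amp) / denom
        r = float(np.abs(f_obs - kiso * amp).sum()) / sum_fobs
        if best is None or r < best[2]:
            best = (float(km), kiso, r)
    if best is None:
        raise UndefinedScaleError("grid refinement has no admissible point")
    return best[0], best[1]
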