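"""Overall anisotropic scale factors: exponential and polynomial models.

The exponential model scales each reflection by

    k_aniso(s) = exp(−2π² sᵗ U_cryst s),        s = (h, k, l),

with U_cryst a symmetric tensor in the Miller-index basis, constrained by
the crystal point group. Taking logarithms reduces the fit to linear least
squares on the log residual Z = (1/2π²) ln(F_obs / A), where A is the model
amplitude with every scale except k_aniso applied: the condition
k_aniso·A = F_obs becomes sᵗ U s = −Z, linear in the six tensor components.
With V(s) = (h², k², l², 2hk, 2hl, 2kl) the normal equations are

    M U = b,   M = Σ V ⊗ V,   b = −Σ Z V,

and point-group constraints enter through the constraint matrix C
(U = Cᵗ U_ind):  (C M Cᵗ) U_ind = C b.

The polynomial model

    k_aniso(s) = 1 + sᵗ V0 s + s² (sᵗ V1 s)

matches the first Taylor terms of the exponential (constant restored so the
factor is exactly 1 at F000) but is linear in its 12 coefficients, so it
minimises the amplitude residual Σ (F_obs − k_aniso·A)² directly with no
log transform and, following its originators, no symmetry constraints.

A third variant polishes the constrained exponential tensor by L-BFGS-B on
the amplitude residual, started from the analytic log-domain solution; the
two residuals have nearby but generally distinct minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .reflection_model import ConstraintMatrix, ReflectionSet

__all__ = [
    "AnisoModel",
    "k_aniso_exponential",
    "k_aniso_polynomial",
    "fit_exponential_aniso",
    "fit_polynomial_aniso",
    "fit_exponential_aniso_minimized",
]

_TWO_PI_SQ = 2.0 * np.pi**2
_COND_LIMIT = 1e12


def _v_terms(indices: np.ndarray) -> np.ndarray:
    """Quadratic index terms V = (h², k², l², 2hk, 2hl, 2kl), shape (n, 6)."""
    hkl = np.asarray(indices, dtype=float)
    h, k, l = hkl.T
    return np.column_stack([h * h, k * k, l * l, 2 * h * k, 2 * h * l, 2 * k * l])


@dataclass
class AnisoModel:
    """Fitted anisotropic scale model of a single kind.

    kind='exponential' populates ``u_cryst`` (Miller-basis symmetric
    6-vector); kind='polynomial' populates ``v0`` and ``v1``. ``converged``
    is only meaningful for the minimized exponential variant.
    """

    kind: str
    u_cryst: np.ndarray | None = None
    v0: np.ndarray | None = None
    v1: np.ndarray | None = None
    n_excluded: int = 0
    converged: bool = True

    def evaluate(self, reflections: ReflectionSet) -> np.ndarray:
        if self.kind == "exponential":
            return k_aniso_exponential(self.u_cryst, reflections.indices)
        return k_aniso_polynomial(self.v0, self.v1, reflections)


def k_aniso_exponential(u_cryst: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """exp(−2π² sᵗ U s) per reflection; equals 1 at (0,0,0)."""
    return np.exp(-_TWO_PI_SQ * (_v_terms(indices) @ np.asarray(u_cryst, float)))


def k_aniso_polynomial(
    v0: np.ndarray, v1: np.ndarray, reflections: ReflectionSet
) -> np.ndarray:
    """1 + sᵗV0 s + s²·(sᵗV1 s) per reflection; equals 1 at (0,0,0)."""
    v = _v_terms(reflections.indices)
    s2 = reflections.s_squared
    return 1.0 + v @ np.asarray(v0, float) + s2 * (v @ np.asarray(v1, float))


def _solve_normal(m: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a normal system by a rank-revealing route; near-singular
    systems (condition > 1e12) fall through to the pseudo-inverse."""
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        sol, *_ = np.linalg.lstsq(m, b, rcond=1e-12)
        return sol
    return np.linalg.solve(m, b)


class RankDeficiencyError(np.linalg.LinAlgError):
    """The anisotropic normal matrix is singular along a stated direction."""


def fit_exponential_aniso(
    f_obs: np.ndarray,
    model_amplitudes: np.ndarray,
    reflections: ReflectionSet,
    constraint: ConstraintMatrix,
) -> AnisoModel:
    """Analytic constrained fit of U_cryst on the log residual.

    ``model_amplitudes`` are |F_model| with every scale except k_aniso
    applied. Reflections with non-positive F_obs or model amplitude cannot
    enter the log and are excluded (their count is recorded on the model).
    """
    f_obs = np.asarray(f_obs, float)
    a = np.asarray(model_amplitudes, float)
    ok = (f_obs > 0) & (a > 0) & np.isfinite(f_obs) & np.isfinite(a)
    n_excluded = int(np.sum(~ok))
    v = _v_terms(reflections.indices)[ok]
    z = np.log(f_obs[ok] / a[ok]) / _TWO_PI_SQ
    c = constraint.rows
    vc = v @ c.T
    m_c = vc.T @ vc
    b_c = -(vc.T @ z)
    cond = np.linalg.cond(m_c)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        w, vec = np.linalg.eigh(m_c)
        bad = vec[:, int(np.argmin(np.abs(w)))]
        raise RankDeficiencyError(
            "singular anisotropic normal matrix; unconstrained direction "
            f"U_ind ~ {np.round(bad, 6).tolist()}"
        )
    u_ind = np.linalg.solve(m_c, b_c)
    return AnisoModel(
        kind="exponential", u_cryst=c.T @ u_ind, n_excluded=n_excluded
    )


def fit_polynomial_aniso(
    f_obs: np.ndarray,
    model_amplitudes: np.ndarray,
    reflections: ReflectionSet,
) -> AnisoModel:
    """Unconstrained 12-parameter linear fit of (V0, V1) on the amplitude
    residual Σ (F_obs − k_aniso·A)²; needs no positivity of the data."""
    f_obs = np.asarray(f_obs, float)
    a = np.asarray(model_amplitudes, float)
    v = _v_terms(reflections.indices)
    s2 = reflections.s_squared
    # residual: F_obs − A − A·(V·v0 + s²·V·v1); linear in (v0, v1)
    design = np.hstack([a[:, None] * v, (a * s2)[:, None] * v])
    rhs = f_obs - a
    m = design.T @ design
    b = design.T @ rhs
    sol = _solve_normal(m, b)
    return AnisoModel(kind="polynomial", v0=sol[:6], v1=sol[6:])


def _safe_exp(x: np.ndarray) -> np.ndarray:
    # guard against overflow on wild quasi-Newton trial steps
    return np.exp(np.clip(x, -60.0, 60.0))


def _amplitude_residual(
    u6: np.ndarray, f_obs: np.ndarray, a: np.ndarray, v: np.ndarray
) -> float:
    k = _safe_exp(-_TWO_PI_SQ * (v @ u6))
    r = f_obs - k * a
    return float(r @ r)


def fit_exponential_aniso_minimized(
    f_obs: np.ndarray,
    model_amplitudes: np.ndarray,
    reflections: ReflectionSet,
    constraint: ConstraintMatrix,
    max_iter: int = 200,
) -> AnisoModel:
    """Constrained exponential fit minimising the amplitude residual by
    L-BFGS-B, started from the analytic log-domain solution. The result is
    never worse (in amplitude residual) than its start."""
    start = fit_exponential_aniso(f_obs, model_amplitudes, reflections, constraint)
    f_obs = np.asarray(f_obs, float)
    a = np.asarray(model_amplitudes, float)
    ok = (f_obs > 0) & (a > 0) & np.isfinite(f_obs) & np.isfinite(a)
    v_ok = _v_terms(reflections.indices)[ok]
    fo, ao = f_obs[ok], a[ok]
    c = constraint.rows

    def fun(u_ind: np.ndarray) -> float:
        return _amplitude_residual(c.T @ u_ind, fo, ao, v_ok)

    def grad(u_ind: np.ndarray) -> np.ndarray:
        u6 = c.T @ u_ind
        k = _safe_exp(-_TWO_PI_SQ * (v_ok @ u6))
        r = fo - k * ao
        # d r_i / d u6 = 2π² a_i k_i V_i
        g6 = 2.0 * _TWO_PI_SQ * ((r * ao * k) @ v_ok)
        return c @ g6

    x0 = constraint.rows @ start.u_cryst  # project back to independent basis
    res = minimize(
        fun, x0, jac=grad, method="L-BFGS-B", options={"maxiter": max_iter}
    )
    best = res.x if fun(res.x) <= fun(x0) else x0
    return AnisoModel(
        kind="exponential",
        u_cryst=c.T @ best,
        n_excluded=start.n_excluded,
        converged=bool(res.success),
    )
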