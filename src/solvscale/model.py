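"""Top-level scaling model: statsmodels-style Model / Results pair.

``ScalingModel`` holds aligned per-reflection data (F_obs, F_calc, F_mask on
one ReflectionSet) and ``fit()`` runs the scaling protocol, returning a
``ScalingResults`` with the full per-reflection decomposition

    F_model = k_total (F_calc + k_mask F_mask),
    k_total = k_overall · k_isotropic · k_anisotropic,

R factors over all / low-resolution / high-resolution reflections, the
fitted anisotropic tensor(s), optional flat-model parameters (k_sol, B_sol)
and twin fractions, and the per-cycle convergence trace.

Protocol. Each cycle first determines (k_mask, k_isotropic) per resolution
bin — by the analytic cubic, Savitzky–Golay smoothing, linear interpolation
in s², an isotropic update by the optimal bin scalar, and an optional
R-factor grid refinement — with the current k_anisotropic divided out of
the working amplitudes; then k_anisotropic is refitted from scratch against
the remaining residual. Cycles repeat until the R factor improves by less
than 0.01% (absolute 1e-4) or the cycle cap is reached; if a cycle makes R
worse the previous state is restored and iteration stops. When several
anisotropic methods are requested each is evaluated and the one with the
lowest R is accepted. Empirically one to five cycles suffice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import aniso, binning, solvent
from .reflection_model import (
    ConstraintMatrix,
    ReflectionSet,
    derive_constraint_matrix,
    u_star_as_cartesian_b,
)
from .twinning import TwinModel, iterate_twin_scaling

logger = logging.getLogger(__name__)

__all__ = ["ScalingModel", "ScalingResults", "ProtocolOptions", "r_factor", "k_overall"]

ANISO_METHODS = ("poly", "exp_anal", "exp_min")
ANISO_CHOICES = ("poly", "exp_anal", "exp_min", "poly+exp_anal", "all", "none")


def r_factor(f_obs: np.ndarray, model_amplitudes: np.ndarray) -> float:
    """Crystallographic R factor Σ|F_obs − |F_model|| / ΣF_obs."""
    f_obs = np.asarray(f_obs, float)
    denom = float(f_obs.sum())
    if denom <= 0:
        raise ZeroDivisionError("sum of F_obs must be positive")
    return float(np.abs(f_obs - np.asarray(model_amplitudes, float)).sum()) / denom


def k_overall(f_obs: np.ndarray, model_amplitudes: np.ndarray) -> float:
    """Optimal overall scalar Σ(F_obs·|F′|)/Σ|F′|² (exact LS minimiser)."""
    a = np.asarray(model_amplitudes, float)
    denom = float(a @ a)
    if denom == 0.0:
        raise ZeroDivisionError("model amplitudes are all zero")
    return float(np.asarray(f_obs, float) @ a) / denom


@dataclass
class ProtocolOptions:
    """Knobs of the scaling protocol.

    aniso_method: 'poly', 'exp_anal', 'exp_min', 'poly+exp_anal' (default,
    best-R of the two fast methods), 'all', or 'none'. r_tol is the absolute
    R-improvement threshold ending the cycle loop (0.0001 = 0.01%).
    """

    aniso_method: str = "poly+exp_anal"
    r_tol: float = 1e-4
    max_cycles: int = 10
    min_count: int = binning.DEFAULT_MIN_COUNT
    max_bins: int = binning.DEFAULT_MAX_BINS
    grid_refine: bool = True
    solvent_first: bool = True  # solvent stage before aniso (empirically best)
    twin_operators: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.aniso_method not in ANISO_CHOICES:
            raise ValueError(f"aniso_method must be one of {ANISO_CHOICES}")
        if self.r_tol <= 0 or self.max_cycles < 1:
            raise ValueError("r_tol must be > 0 and max_cycles >= 1")

    @property
    def methods(self) -> tuple[str, ...]:
        if self.aniso_method == "none":
            return ()
        if self.aniso_method == "all":
            return ANISO_METHODS
        if self.aniso_method == "poly+exp_anal":
            return ("poly", "exp_anal")
        return (self.aniso_method,)


@dataclass
class ScalingResults:
    """Fitted scales, R factors and diagnostics of one protocol run."""

    model: "ScalingModel"
    options: ProtocolOptions
    k_overall: float
    k_isotropic: np.ndarray
    k_anisotropic: np.ndarray
    k_mask: np.ndarray
    solvent_scales: solvent.SolventScales
    aniso_model: aniso.AnisoModel | None
    aniso_method: str
    twin_model: TwinModel | None
    cycles: int
    r_trace: list
    r_all: float = field(init=False)
    r_low: float = field(init=False)
    r_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.r_all, self.r_low, self.r_high = self.resolution_partition_report()

    @property
    def k_total(self) -> np.ndarray:
        return self.k_overall * self.k_isotropic * self.k_anisotropic

    @property
    def f_model(self) -> np.ndarray:
        """|F_model| = k_total · |F_calc + k_mask · F_mask| per reflection."""
        return self.k_total * np.abs(
            self.model.f_calc + self.k_mask * self.model.f_mask
        )

    def resolution_partition_report(
        self, low_d_cut: float = 8.0, min_low_count: int = 500
    ) -> tuple[float, float, float]:
        """R over all reflections, over the low-resolution subset (d > 8 Å
        but at least the 500 lowest-resolution reflections) and over the
        highest-resolution bin."""
        f_obs = self.model.f_obs
        fm = self.f_model
        d = self.model.reflections.d
        low = d > low_d_cut
        if int(low.sum()) < min_low_count:
            order = np.argsort(-d)
            low = np.zeros(len(d), dtype=bool)
            low[order[: min(min_low_count, len(d))]] = True
        high = self._highest_bin_mask()
        r_all = r_factor(f_obs, fm)
        r_low = r_factor(f_obs[low], fm[low]) if low.any() else r_all
        r_high = r_factor(f_obs[high], fm[high]) if high.any() else r_all
        return r_all, r_low, r_high

    def _highest_bin_mask(self) -> np.ndarray:
        part = getattr(self, "_partition", None)
        if part is None:
            part = binning.log_d_bins(
                self.model.reflections.d,
                min_count=self.options.min_count,
                max_bins=self.options.max_bins,
            )
        return part.bin_of == part.n_bins - 1

    def summary(self) -> str:
        lines = [
            "Bulk-solvent and anisotropic scaling",
            "=" * 52,
            f"reflections:        {len(self.model.f_obs)}",
            f"resolution range:   {self.model.reflections.d.max():.2f} - "
            f"{self.model.reflections.d.min():.2f} A",
            f"aniso method:       {self.aniso_method}",
            f"cycles:             {self.cycles}",
            f"k_overall:          {self.k_overall:.6g}",
            f"R(all):             {self.r_all:.4f}",
            f"R(low, d>8A|500):   {self.r_low:.4f}",
            f"R(high bin):        {self.r_high:.4f}",
        ]
        ss = self.solvent_scales
        if ss.k_sol is not None:
            lines.append(f"k_sol, B_sol:       {ss.k_sol:.4f}, {ss.b_sol:.2f} A^2")
        if self.aniso_model is not None and self.aniso_model.kind == "exponential":
            b_cart = u_star_as_cartesian_b(
                self.aniso_model.u_cryst, self.model.reflections.cell
            )
            lines.append(
                "B_cart (11,22,33):  "
                + ", ".join(f"{x:.2f}" for x in b_cart[:3])
            )
        if self.twin_model is not None:
            fr = ", ".join(f"{a:.4f}" for a in self.twin_model.fractions)
            lines.append(f"twin fractions:     {fr}")
        lines.append("per-cycle R: " + ", ".join(f"{r:.5f}" for r in self.r_trace))
        return "\n".join(lines)

    def bin_table(self) -> "pandas.DataFrame":
        import pandas as pd

        ss = self.solvent_scales
        part = self._partition
        counts = part.counts
        rows = []
        for b in range(part.n_bins):
            sel = part.bin_of == b
            rows.append(
                {
                    "d_max": part.boundaries[b],
                    "d_min": part.boundaries[b + 1],
                    "count": int(counts[b]),
                    "k_total": ss.k_total_bins[b],
                    "k_mask": ss.k_mask_bins[b],
                    "k_mask_smoothed": ss.k_mask_bins_smoothed[b],
                    "r_bin": r_factor(self.model.f_obs[sel], self.f_model[sel]),
                }
            )
        return pd.DataFrame(rows)


class ScalingModel:
    """Scaling model for one set of observed and calculated structure factors.

    Parameters
    ----------
    f_obs : (n,) non-negative observed amplitudes.
    f_calc, f_mask : (n,) complex structure factors from the atomic model
        and from the bulk-solvent mask, aligned with ``f_obs``.
    reflections : ReflectionSet carrying indices, cell and point group.
    """

    def __init__(self, f_obs, f_calc, f_mask, reflections: ReflectionSet):
        self.f_obs = np.asarray(f_obs, float)
        self.f_calc = np.asarray(f_calc, complex)
        self.f_mask = np.asarray(f_mask, complex)
        self.reflections = reflections
        n = len(reflections)
        for name, arr in (("f_obs", self.f_obs), ("f_calc", self.f_calc),
                          ("f_mask", self.f_mask)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if not np.all(np.isfinite(arr.view(float))):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.f_obs < 0):
            raise ValueError("f_obs must be non-negative")
        if n < 10:
            raise ValueError("need at least 10 reflections")
        self.constraint: ConstraintMatrix = derive_constraint_matrix(
            reflections.rotations
        )

    @classmethod
    def from_dataframe(cls, frame, cell, spacegroup: str = "P 1") -> "ScalingModel":
        """Build from a DataFrame with columns h, k, l, f_obs, f_calc_re,
        f_calc_im, f_mask_re, f_mask_im."""
        refl = ReflectionSet.from_symbol(
            frame[["h", "k", "l"]].to_numpy(int), cell, spacegroup
        )
        return cls(
            frame["f_obs"].to_numpy(float),
            frame["f_calc_re"].to_numpy(float) + 1j * frame["f_calc_im"].to_numpy(float),
            frame["f_mask_re"].to_numpy(float) + 1j * frame["f_mask_im"].to_numpy(float),
            refl,
        )

    # ------------------------------------------------------------------ fit

    def fit(self, options: ProtocolOptions | None = None, **kwargs) -> ScalingResults:
        """Run the scaling protocol and return a ScalingResults."""
        if options is None:
            options = ProtocolOptions(**kwargs)
        elif kwargs:
            raise TypeError("pass either options or keyword arguments, not both")
        if options.twin_operators is not None and len(options.twin_operators) > 1:
            return self._fit_twinned(options)
        return self._fit_untwinned(options)

    def _solvent_stage(self, options, part, centers, k_aniso):
        """One (k_mask, k_isotropic) determination with k_aniso divided out.

        Returns per-reflection (k_iso_work, k_mask) plus the per-bin arrays.
        The working isotropic scale absorbs k_overall; the product is split
        at reporting time.
        """
        f_obs_w = self.f_obs / k_aniso
        nb = part.n_bins
        k_mask_bins = np.zeros(nb)
        k_total_bins = np.ones(nb)
        for b in range(nb):
            sel = part.bin_of == b
            m = solvent.bin_moments(self.f_calc[sel], self.f_mask[sel], f_obs_w[sel])
            k_big, km, _ = solvent.solve_bin_scales(m)
            k_mask_bins[b] = km
            k_total_bins[b] = k_big ** -0.5
        k_mask_sm = solvent.smooth_kmask(k_mask_bins)

        # isotropic update (optimal bin scalar at the smoothed k_mask),
        # optional R-factor grid refinement per bin
        k_iso_bins = np.zeros(nb)
        k_mask_ref = k_mask_sm.copy()
        for b in range(nb):
            sel = part.bin_of == b
            amp = np.abs(self.f_calc[sel] + k_mask_sm[b] * self.f_mask[sel])
            k_iso_bins[b] = solvent.update_kisotropic(f_obs_w[sel], amp)
            if options.grid_refine:
                km, ki = solvent.rfactor_grid_refine(
                    f_obs_w[sel], self.f_calc[sel], self.f_mask[sel],
                    k_mask_sm[b], k_iso_bins[b],
                )
                k_mask_ref[b], k_iso_bins[b] = km, ki
        s2 = self.reflections.s_squared
        k_mask = solvent.interpolate_scales(k_mask_ref, centers, s2)
        k_iso = solvent.interpolate_scales(k_iso_bins, centers, s2)
        return k_iso, k_mask, k_mask_bins, k_mask_ref, k_iso_bins, k_total_bins

    def _aniso_stage(self, method, k_iso, k_mask):
        amp = k_iso * np.abs(self.f_calc + k_mask * self.f_mask)
        if method == "poly":
            mdl = aniso.fit_polynomial_aniso(self.f_obs, amp, self.reflections)
        elif method == "exp_anal":
            mdl = aniso.fit_exponential_aniso(
                self.f_obs, amp, self.reflections, self.constraint
            )
        else:
            mdl = aniso.fit_exponential_aniso_minimized(
                self.f_obs, amp, self.reflections, self.constraint
            )
        return mdl, mdl.evaluate(self.reflections)

    def _fit_untwinned(self, options: ProtocolOptions) -> ScalingResults:
        part = binning.log_d_bins(
            self.reflections.d, min_count=options.min_count, max_bins=options.max_bins
        )
        centers = part.centers_s2()

        k_aniso = np.ones_like(self.f_obs)
        aniso_model = None
        method_used = "none"
        state = None
        prev_r = None
        r_trace = []
        cycles = 0
        for cycle in range(1, options.max_cycles + 1):
            k_iso, k_mask, km_raw, km_sm, ki_bins, kt_bins = self._solvent_stage(
                options, part, centers, k_aniso
            )
            best = None
            if options.methods:
                for method in options.methods:
                    try:
                        mdl, ka = self._aniso_stage(method, k_iso, k_mask)
                    except aniso.RankDeficiencyError:
                        logger.warning("aniso method %s rank-deficient; skipped",
                                       method)
                        continue
                    ka = np.clip(ka, 1e-6, None)
                    amp = k_iso * ka * np.abs(self.f_calc + k_mask * self.f_mask)
                    r = r_factor(self.f_obs, amp)
                    if best is None or r < best[0]:
                        best = (r, method, mdl, ka)
            if best is None:
                ka = np.ones_like(self.f_obs)
                amp = k_iso * np.abs(self.f_calc + k_mask * self.f_mask)
                best = (r_factor(self.f_obs, amp), "none", None, ka)
            r, method_cycle, mdl_cycle, ka = best
            new_state = (k_iso, k_mask, km_raw, km_sm, ki_bins, kt_bins,
                         mdl_cycle, method_cycle, ka)
            if prev_r is not None and r > prev_r:
                logger.info("cycle %d increased R (%.6f > %.6f); restoring",
                            cycle, r, prev_r)
                break
            state = new_state
            r_trace.append(r)
            cycles = cycle
            k_aniso = ka
            if prev_r is not None and prev_r - r < options.r_tol:
                prev_r = r
                break
            prev_r = r

        (k_iso, k_mask, km_raw, km_sm, ki_bins, kt_bins,
         aniso_model, method_used, k_aniso) = state

        return self._package(
            options, part, centers, k_iso, k_mask, km_raw, km_sm, ki_bins,
            kt_bins, k_aniso, aniso_model, method_used, None, cycles, r_trace
        )

    def _fit_twinned(self, options: ProtocolOptions) -> ScalingResults:
        twin_model, scales = iterate_twin_scaling(
            self.f_obs, self.f_calc, self.f_mask, self.reflections,
            options.twin_operators,
            min_count=options.min_count, max_bins=options.max_bins,
            max_iter=options.max_cycles,
        )
        part = binning.log_d_bins(
            self.reflections.d, min_count=options.min_count, max_bins=options.max_bins
        )
        centers = part.centers_s2()
        k_aniso = np.ones_like(self.f_obs)
        return self._package(
            options, part, centers, scales.k_isotropic, scales.k_mask,
            scales.k_mask_bins, scales.k_mask_bins_smoothed,
            scales.k_isotropic_bins, scales.k_total_bins, k_aniso,
            None, "none", twin_model, options.max_cycles, [],
        )

    def _package(self, options, part, centers, k_iso_work, k_mask, km_raw,
                 km_sm, ki_bins, kt_bins, k_aniso, aniso_model, method_used,
                 twin_model, cycles, r_trace) -> ScalingResults:
        # Split the working isotropic curve into a scalar k_overall and a
        # normalised k_isotropic: normalise by the mean per-bin value, then
        # set k_overall to the optimal overall scalar given everything else.
        m = float(np.mean(ki_bins)) if np.mean(ki_bins) > 0 else 1.0
        k_iso_norm = k_iso_work / m
        amp = k_iso_norm * k_aniso * np.abs(self.f_calc + k_mask * self.f_mask)
        k_ov = k_overall(self.f_obs, amp)

        ss = solvent.SolventScales(
            k_mask_bins=km_raw,
            k_mask_bins_smoothed=km_sm,
            k_total_bins=kt_bins,
            k_isotropic_bins=ki_bins / m,
            bin_centers_s2=centers,
            k_mask=k_mask,
            k_isotropic=k_iso_norm,
        )
        fit = solvent.fit_ksol_bsol(km_sm, centers)
        if fit is not None:
            ss.k_sol, ss.b_sol = fit
        fit2 = solvent.fit_koverall_boverall(ki_bins, centers)
        if fit2 is not None:
            ss.k_overall, ss.b_overall = fit2

        res = ScalingResults(
            model=self,
            options=options,
            k_overall=k_ov,
            k_isotropic=k_iso_norm,
            k_anisotropic=k_aniso,
            k_mask=k_mask,
            solvent_scales=ss,
            aniso_model=aniso_model,
            aniso_method=method_used,
            twin_model=twin_model,
            cycles=cycles,
            r_trace=r_trace,
        )
        res._partition = part
        return res
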