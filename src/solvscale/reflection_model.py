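"""Crystallographic data model: unit cells, Miller indices, resolution and
point-group symmetry constraints on symmetric tensors.

The central quantities are the reciprocal-space metric tensor ``G*`` of the
unit cell, the squared reciprocal-vector length ``s² = sᵗ G* s`` of a
reflection ``s = (h, k, l)`` (units Å⁻²; the resolution is ``d = 1/|s|``),
and the linear constraints that crystal point-group symmetry imposes on a
symmetric 3×3 tensor expressed in the Miller-index basis: ``Rᵗ U R = U`` for
every rotation ``R`` of the point group acting on Miller indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "ReflectionSet",
    "ConstraintMatrix",
    "reciprocal_metric_tensor",
    "s_squared",
    "point_group_rotations",
    "derive_constraint_matrix",
    "expand_independent",
    "u_star_as_cartesian_b",
]

# Symmetric 3x3 tensor <-> 6-vector convention used throughout:
# (U11, U22, U33, U12, U13, U23).
_SYM_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


class InvalidCellError(ValueError):
    """Unit cell is degenerate (non-positive volume)."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180) degrees")

    def direct_basis(self) -> np.ndarray:
        """Direct-space basis vectors as rows (standard PDB orthogonalisation)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos([al, be, ga])
        sg = np.sin(ga)
        cz = (ca - cb * cg) / sg
        zsq = 1.0 - cb * cb - cz * cz
        if zsq <= 1e-12:
            raise InvalidCellError("degenerate unit cell (near-zero volume)")
        va = np.array([self.a, 0.0, 0.0])
        vb = np.array([self.b * cg, self.b * sg, 0.0])
        vc = np.array([self.c * cb, self.c * cz, self.c * np.sqrt(zsq)])
        return np.vstack([va, vb, vc])

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.direct_basis())))

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def reciprocal_metric_tensor(cell: UnitCell) -> np.ndarray:
    """Reciprocal-space metric tensor ``G*`` with ``s² = sᵗ G* s``.

    ``G*`` is the inverse of the direct-space metric tensor ``G = A Aᵗ``
    built from the cell basis vectors; it is symmetric positive definite.
    """
    basis = cell.direct_basis()
    g_direct = basis @ basis.T
    g_star = np.linalg.inv(g_direct)
    return 0.5 * (g_star + g_star.T)


def s_squared(indices: np.ndarray, g_star: np.ndarray) -> np.ndarray:
    """Per-reflection ``s² = sᵗ G* s`` (Å⁻²) for integer Miller indices."""
    hkl = np.asarray(indices, dtype=float)
    return np.einsum("ij,jk,ik->i", hkl, g_star, hkl)


def point_group_rotations(symbol_or_rotations) -> np.ndarray:
    """Resolve point-group rotations acting on Miller indices.

    Accepts a Hermann–Mauguin space-group symbol (resolved through gemmi;
    translation parts are dropped) or an explicit iterable of 3×3 integer
    matrices. Rotations returned act on the Miller-index column vector:
    for a symmetry operation with fractional-coordinate matrix ``W`` the
    Miller indices transform by ``Wᵗ``.
    """
    if isinstance(symbol_or_rotations, str):
        sg = gemmi.find_spacegroup_by_name(symbol_or_rotations)
        if sg is None:
            raise ValueError(f"unknown space-group symbol: {symbol_or_rotations!r}")
        den = gemmi.Op.DEN
        rots = []
        for op in sg.operations():
            w = np.array(op.rot, dtype=float) / den
            rots.append(np.rint(w.T).astype(int))
        uniq = {tuple(r.ravel()) for r in rots}
        return np.array(sorted(uniq)).reshape(-1, 3, 3)
    rots = np.asarray(list(symbol_or_rotations), dtype=int)
    if rots.ndim != 3 or rots.shape[1:] != (3, 3):
        raise ValueError("rotations must be a list of 3x3 integer matrices")
    return rots


@dataclass
class ReflectionSet:
    """Unique Miller indices on one lattice with derived resolution data.

    Assumes one record per unique index (merging happens upstream, in I/O).
    """

    indices: np.ndarray
    cell: UnitCell
    rotations: np.ndarray = field(default=None)  # point group, incl. identity

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("indices must be an (n, 3) integer array")
        if self.rotations is None:
            self.rotations = np.eye(3, dtype=int)[None]
        self.g_star = reciprocal_metric_tensor(self.cell)
        self.s_squared = s_squared(self.indices, self.g_star)

    @classmethod
    def from_symbol(cls, indices, cell: UnitCell, symbol: str) -> "ReflectionSet":
        return cls(indices, cell, point_group_rotations(symbol))

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def d(self) -> np.ndarray:
        """Resolution d = 1/|s| in Å (inf for the (0,0,0) reflection)."""
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(self.s_squared)


@dataclass(frozen=True)
class ConstraintMatrix:
    """Linear map from independent tensor components to the 6-vector
    (U11, U22, U33, U12, U13, U23); ``rows`` has shape (n_independent, 6)."""

    rows: np.ndarray

    @property
    def n_independent(self) -> int:
        return self.rows.shape[0]

    def expand(self, u_ind: np.ndarray) -> np.ndarray:
        return expand_independent(u_ind, self)


def _sym6_to_mat(u6: np.ndarray) -> np.ndarray:
    m = np.empty((3, 3))
    for k, (i, j) in enumerate(_SYM_IDX):
        m[i, j] = m[j, i] = u6[k]
    return m


def _mat_to_sym6(m: np.ndarray) -> np.ndarray:
    return np.array([m[i, j] for i, j in _SYM_IDX])


def derive_constraint_matrix(rotations, tol: float = 1e-9) -> ConstraintMatrix:
    """Derive symmetry constraints on a symmetric tensor from first principles.

    Solves ``Rᵗ U R = U`` for all point-group rotations ``R`` by computing the
    null space of the stacked linear maps ``U ↦ Rᵗ U R − U`` over the 6-dim
    space of symmetric tensors. The returned basis is orthonormal, with the
    sign fixed so the first nonzero element of each row is positive, making
    the independent-parameter basis deterministic.
    """
    rots = np.asarray(rotations, dtype=float)
    blocks = []
    for r in rots:
        m = np.empty((6, 6))
        for k in range(6):
            e = np.zeros(6)
            e[k] = 1.0
            u = _sym6_to_mat(e)
            m[:, k] = _mat_to_sym6(r.T @ u @ r - u)
        blocks.append(m)
    stacked = np.vstack(blocks)
    _, sv, vt = np.linalg.svd(stacked)
    rank = int(np.sum(sv > tol * (sv[0] if sv.size and sv[0] > 0 else 1.0)))
    null = vt[rank:]
    if null.size == 0:
        raise ValueError("no invariant symmetric tensor (rotations inconsistent)")
    # Deterministic orientation: RQ-like cleanup via another SVD already gives
    # an orthonormal basis; fix signs and row order.
    rows = []
    for row in null:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            row = -row
        rows.append(row)
    rows = np.array(sorted(rows, key=lambda r: tuple(np.round(r, 12))))
    return ConstraintMatrix(rows)


def expand_independent(u_ind: np.ndarray, constraint: ConstraintMatrix) -> np.ndarray:
    """Expand independent components to the full symmetric 6-vector
    via ``U = Cᵗ U_ind``."""
    u_ind = np.asarray(u_ind, dtype=float)
    if u_ind.shape != (constraint.n_independent,):
        raise ValueError(
            f"expected {constraint.n_independent} independent components, "
            f"got shape {u_ind.shape}"
        )
    return constraint.rows.T @ u_ind


def u_star_as_cartesian_b(u6: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Report a Miller-basis scale tensor as Cartesian B values (Å²).

    Converts ``U*`` (Miller-index basis, as used in exp(−2π² sᵗ U* s)) to the
    Cartesian displacement convention and multiplies by 8π²: with direct
    basis rows ``A`` (so fractionalisation F = A⁻¹ and s_cart = Fᵗ s_hkl is
    the reciprocal vector), ``U_cart = Aᵗ U* A`` and ``B = 8π² U_cart``.
    """
    a = UnitCell.direct_basis(cell)
    u = _sym6_to_mat(np.asarray(u6, dtype=float))
    u_cart = a.T @ u @ a
    return _mat_to_sym6(8.0 * np.pi**2 * u_cart)
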