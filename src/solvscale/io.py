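"""Reflection-file readers/writers and result serialization.

Three formats are supported: MTZ and mmCIF (refln loop) through gemmi, and
a plain whitespace-separated text dialect with the fixed column header

    h k l f_obs f_calc_re f_calc_im f_mask_re f_mask_im

Phases in text formats are always degrees. Friedel mates are merged on
read (F_obs averaged) by default, since the scaling model is
Friedel-symmetric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .reflection_model import ReflectionSet, UnitCell

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnBinding",
    "read_reflections",
    "write_reflections_tsv",
    "write_mtz",
    "write_result",
]

TSV_COLUMNS = ["h", "k", "l", "f_obs", "f_calc_re", "f_calc_im", "f_mask_re", "f_mask_im"]


class ReflectionFileError(ValueError):
    """Problem reading a reflection file (missing columns, empty file...)."""


@dataclass
class ColumnBinding:
    """Column labels binding F_obs / F_calc / F_mask in an MTZ or mmCIF
    file. Complex columns may be (amplitude, phase-in-degrees) pairs."""

    f_obs: str = "FOBS"
    f_calc: tuple = ("FC", "PHIC")
    f_mask: tuple = ("FMASK", "PHIMASK")


def _merge_friedel(df: pd.DataFrame) -> pd.DataFrame:
    """Average F_obs over Friedel pairs, keeping one hemisphere."""
    hkl = df[["h", "k", "l"]].to_numpy(int)
    neg = (hkl[:, 2] < 0) | (
        (hkl[:, 2] == 0) & ((hkl[:, 1] < 0) | ((hkl[:, 1] == 0) & (hkl[:, 0] < 0)))
    )
    canon = np.where(neg[:, None], -hkl, hkl)
    out = df.copy()
    out[["h", "k", "l"]] = canon
    # conjugate complex parts for inverted indices
    for col in ("f_calc_im", "f_mask_im"):
        out[col] = np.where(neg, -out[col], out[col])
    grouped = out.groupby(["h", "k", "l"], as_index=False).agg(
        {c: "mean" for c in TSV_COLUMNS[3:]}
    )
    return grouped


def read_reflections(
    path,
    binding: ColumnBinding | None = None,
    cell: UnitCell | None = None,
    spacegroup: str | None = None,
    merge: bool = True,
):
    """Read reflections and return (ReflectionSet, f_obs, f_calc, f_mask).

    Format is chosen by extension: .mtz, .cif/.mmcif, else the TSV dialect.
    Cell and space group come from the file header unless overridden.
    """
    path = str(path)
    if path.endswith(".mtz"):
        df, fcell, fsg = _read_mtz(path, binding or ColumnBinding())
    elif path.endswith((".cif", ".mmcif")):
        df, fcell, fsg = _read_mmcif(path, binding or ColumnBinding())
    else:
        df, fcell, fsg = _read_tsv(path)
    cell = cell or fcell
    spacegroup = spacegroup or fsg or "P 1"
    if cell is None:
        raise ReflectionFileError("no unit cell in file; pass cell explicitly")
    if df.empty:
        raise ReflectionFileError(f"no reflections in {path}")
    bad = ~np.isfinite(df[TSV_COLUMNS[3:]].to_numpy(float)).all(axis=1)
    bad |= df["f_obs"].to_numpy(float) < 0
    if bad.any():
        logger.warning("%d reflections dropped (non-finite or negative F_obs)",
                       int(bad.sum()))
        df = df[~bad]
    if merge:
        df = _merge_friedel(df)
    refl = ReflectionSet.from_symbol(
        df[["h", "k", "l"]].to_numpy(int), cell, spacegroup
    )
    f_obs = df["f_obs"].to_numpy(float)
    f_calc = df["f_calc_re"].to_numpy(float) + 1j * df["f_calc_im"].to_numpy(float)
    f_mask = df["f_mask_re"].to_numpy(float) + 1j * df["f_mask_im"].to_numpy(float)
    return refl, f_obs, f_calc, f_mask


def _read_tsv(path):
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        raise ReflectionFileError(f"empty reflection file: {path}") from None
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ReflectionFileError(f"missing columns in {path}: {missing}")
    return df[TSV_COLUMNS], None, None


def _columns_to_df(hkl, f_obs, f_calc, f_mask) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "f_obs": f_obs,
            "f_calc_re": f_calc.real,
            "f_calc_im": f_calc.imag,
            "f_mask_re": f_mask.real,
            "f_mask_im": f_mask.imag,
        }
    )


def _complex_from(columns, df_get, label: str):
    """Complex array from a (re, im) or (amplitude, phase-degrees) pair."""
    a_label, b_label = columns
    a = df_get(a_label)
    b = df_get(b_label)
    if a_label.lower().endswith("_re") or b_label.lower().endswith("_im"):
        return a + 1j * b
    return a * np.exp(1j * np.radians(b))  # amplitude + phase in degrees


def _read_mtz(path, binding: ColumnBinding):
    mtz = gemmi.read_mtz_file(path)
    labels = [c.label for c in mtz.columns]

    def get(label):
        if label not in labels:
            raise ReflectionFileError(f"MTZ column {label!r} not found in {path}")
        return np.asarray(mtz.column_with_label(label).array, float)

    hkl = np.column_stack([get("H"), get("K"), get("L")]).astype(int)
    f_obs = get(binding.f_obs)
    f_calc = _complex_from(binding.f_calc, get, "f_calc")
    f_mask = _complex_from(binding.f_mask, get, "f_mask")
    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c,
                    mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    sg = mtz.spacegroup.hm if mtz.spacegroup else None
    return _columns_to_df(hkl, f_obs, f_calc, f_mask), cell, sg


def _read_mmcif(path, binding: ColumnBinding):
    doc = gemmi.cif.read(str(path))
    rblocks = gemmi.as_refln_blocks(doc)
    if not rblocks:
        raise ReflectionFileError(f"no refln loop in {path}")
    rb = rblocks[0]

    def get(label):
        arr = rb.make_float_array(label)
        if arr.size == 0:
            raise ReflectionFileError(f"mmCIF column {label!r} not found in {path}")
        return np.asarray(arr, float)

    hkl = np.asarray(rb.make_miller_array(), int)
    f_obs = get(binding.f_obs)
    f_calc = _complex_from(binding.f_calc, get, "f_calc")
    f_mask = _complex_from(binding.f_mask, get, "f_mask")
    c = rb.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma) if c.a > 0 else None
    sg = rb.spacegroup.hm if rb.spacegroup else None
    return _columns_to_df(hkl, f_obs, f_calc, f_mask), cell, sg


def write_reflections_tsv(path, reflections: ReflectionSet, f_obs, f_calc, f_mask):
    """Write the TSV dialect; floats at 12 significant digits so data
    survive a round trip to 1e-10 relative."""
    df = _columns_to_df(reflections.indices, np.asarray(f_obs, float),
                        np.asarray(f_calc, complex), np.asarray(f_mask, complex))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_mtz(path, reflections: ReflectionSet, f_obs, f_calc, f_mask,
              spacegroup: str = "P 1"):
    """Write an MTZ with FOBS and amplitude/phase pairs FC/PHIC, FMASK/PHIMASK."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.find_spacegroup_by_name(spacegroup)
    c = reflections.cell
    mtz.set_cell_for_all(gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
    mtz.add_dataset("solvscale")
    mtz.add_column("FOBS", "F")
    mtz.add_column("FC", "F")
    mtz.add_column("PHIC", "P")
    mtz.add_column("FMASK", "F")
    mtz.add_column("PHIMASK", "P")
    f_calc = np.asarray(f_calc, complex)
    f_mask = np.asarray(f_mask, complex)
    data = np.column_stack([
        reflections.indices.astype(float),
        np.asarray(f_obs, float),
        np.abs(f_calc), np.degrees(np.angle(f_calc)),
        np.abs(f_mask), np.degrees(np.angle(f_mask)),
    ])
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def result_to_dict(result) -> dict:
    """JSON-ready dict of a ScalingResults (schema 1)."""
    ss = result.solvent_scales
    out = {
        "schema": 1,
        "n_reflections": int(len(result.model.f_obs)),
        "aniso_method": result.aniso_method,
        "cycles": int(result.cycles),
        "r_all": result.r_all,
        "r_low": result.r_low,
        "r_high": result.r_high,
        "r_trace": [float(r) for r in result.r_trace],
        "k_overall": result.k_overall,
        "k_sol": ss.k_sol,
        "b_sol": ss.b_sol,
        "bins": {
            "centers_s2": ss.bin_centers_s2.tolist(),
            "k_mask": ss.k_mask_bins.tolist(),
            "k_mask_smoothed": ss.k_mask_bins_smoothed.tolist(),
            "k_isotropic": ss.k_isotropic_bins.tolist(),
        },
    }
    if result.aniso_model is not None:
        am = result.aniso_model
        from .reflection_model import u_star_as_cartesian_b

        if am.kind == "exponential":
            out["u_cryst"] = am.u_cryst.tolist()
            out["b_cartesian"] = u_star_as_cartesian_b(
                am.u_cryst, result.model.reflections.cell
            ).tolist()
        else:
            out["v0"] = am.v0.tolist()
            out["v1"] = am.v1.tolist()
    if result.twin_model is not None:
        out["twin_fractions"] = result.twin_model.fractions.tolist()
    return out


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_result(result, path) -> None:
    """Serialize a ScalingResults to JSON with stable key order and floats
    at 12 significant digits (write→read→write is byte-stable)."""
    payload = _round_floats(result_to_dict(result))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
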