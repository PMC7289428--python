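"""CSV readers and writers for spectra, species records and loci tables."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SpectralFunction
from .vision import classify_sector, hue_and_contrast

logger = logging.getLogger(__name__)

__all__ = [
    "read_spectra_csv",
    "read_spectrum_csv",
    "read_records_csv",
    "write_loci_csv",
]


def _to_fraction(values: np.ndarray, unit: str | None) -> np.ndarray:
    """Reflectance to fraction; percent auto-detected by max value > 1.5."""
    if unit == "percent" or (unit is None and np.nanmax(values) > 1.5):
        return values / 100.0
    return values


def read_spectra_csv(
    path: str | Path, unit: str | None = None
) -> dict[str, list[tuple[str, float | None, SpectralFunction]]]:
    """Read flower reflectance spectra in long or wide form.

    Long form: columns ``species, wavelength_nm, reflectance`` (or
    ``reflectance_pct``) with optional ``patch`` and ``area_fraction``
    columns for multi-coloured flowers.  Wide form: first column
    ``wavelength_nm``, one column per species.  Reflectance may be
    percent [0, 100] or fraction [0, 1]; auto-detected unless ``unit``
    is ``"percent"`` or ``"fraction"``.

    Returns a mapping species → list of (patch, area_fraction, spectrum).
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    out: dict[str, list[tuple[str, float | None, SpectralFunction]]] = {}
    if "species" in cols:  # long form
        wl_col = cols.get("wavelength_nm") or cols.get("wavelength")
        refl_col = cols.get("reflectance_pct") or cols.get("reflectance")
        if wl_col is None or refl_col is None:
            raise ValueError("long-form spectra need wavelength and reflectance columns")
        if cols.get("reflectance_pct") and unit is None:
            unit = "percent"
        patch_col = cols.get("patch")
        area_col = cols.get("area_fraction")
        group_cols = [cols["species"]] + ([patch_col] if patch_col else [])
        for key, grp in df.groupby(group_cols, sort=False):
            species = key[0] if isinstance(key, tuple) else key
            patch = str(key[1]) if patch_col else "1"
            grp = grp.sort_values(wl_col)
            vals = _to_fraction(grp[refl_col].to_numpy(dtype=float), unit)
            area = float(grp[area_col].iloc[0]) if area_col else None
            sf = SpectralFunction(grp[wl_col].to_numpy(dtype=float), vals)
            out.setdefault(str(species), []).append((patch, area, sf))
    else:  # wide form
        wl = df.iloc[:, 0].to_numpy(dtype=float)
        order = np.argsort(wl)
        for col in df.columns[1:]:
            vals = _to_fraction(df[col].to_numpy(dtype=float)[order], unit)
            out[str(col)] = [("1", None, SpectralFunction(wl[order], vals))]
    return out


def read_spectrum_csv(path: str | Path) -> SpectralFunction:
    """Read a single two-column (wavelength_nm, value) spectrum."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: wavelength_nm, value")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    vals = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wl)
    return SpectralFunction(wl[order], _to_fraction(vals[order], None))


_RECORD_ALIASES = {
    "species": ("species", "name", "taxon"),
    "family": ("family",),
    "site": ("site", "location"),
    "sugar_ug": ("sugar_ug", "sucrose_ug", "sugar", "sucrose_amount"),
    "x": ("x", "hex_x", "hexagon_x"),
    "y": ("y", "hex_y", "hexagon_y"),
}


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read a species table with precomputed hexagon coordinates.

    Mandatory columns (by any common alias): species, sugar amount in μg
    and the hexagon (x, y).  Hue, chromatic contrast and colour sector
    are recomputed from (x, y).  A sugar column whose maximum is below
    10 is flagged as likely mis-scaled (mg rather than μg).
    """
    df = pd.read_csv(path)
    lower = {c.lower().strip(): c for c in df.columns}
    found = {}
    for target, aliases in _RECORD_ALIASES.items():
        for a in aliases:
            if a in lower:
                found[target] = lower[a]
                break
    for required in ("species", "sugar_ug", "x", "y"):
        if required not in found:
            raise ValueError(f"records CSV lacks a recognizable {required!r} column")
    out = pd.DataFrame(
        {
            "species": df[found["species"]].astype(str),
            "family": df[found["family"]].astype(str) if "family" in found else "",
            "site": df[found["site"]].astype(str) if "site" in found else "",
            "sugar_ug": pd.to_numeric(df[found["sugar_ug"]], errors="raise"),
            "x": pd.to_numeric(df[found["x"]], errors="raise"),
            "y": pd.to_numeric(df[found["y"]], errors="raise"),
        }
    )
    if out["sugar_ug"].max() < 10:
        logger.warning(
            "max sugar %.3g < 10: values may be in mg, expected μg",
            out["sugar_ug"].max(),
        )
    hues, contrasts, sectors = [], [], []
    for x, y in zip(out["x"], out["y"]):
        hue, contrast = hue_and_contrast(float(x), float(y))
        hues.append(hue)
        contrasts.append(contrast)
        sectors.append(classify_sector(hue) if hue is not None else None)
    out["hue_deg"] = hues
    out["contrast"] = contrasts
    out["sector"] = sectors
    return out


def write_loci_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the per-species locus table (S1-style columns)."""
    cols = [
        c
        for c in (
            "species", "family", "site", "sugar_ug",
            "E_UV", "E_B", "E_G", "x", "y", "hue_deg", "contrast", "sector",
        )
        if c in frame.columns
    ]
    frame[cols].to_csv(path, index=False)
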