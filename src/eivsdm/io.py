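"""Readers, writers and the run manifest.

All tabular interchange is CSV (comma, UTF-8, "." decimal); raster layers
are written as ESRI ASCII grids, a plain-text format any GIS reads.
Relevé tables are accepted in long format (one row per plot x species
occurrence) or wide 0/1 format and auto-detected from the header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import LandscapeBundle, PlotCommunityMatrix
from .site_eiv import SiteEIVMatrix, SpeciesEIVTable

__all__ = [
    "DataValidationError",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_landscape",
    "write_plots_csv",
    "write_presence_csv",
    "read_releve_table",
    "write_species_eivs",
    "read_species_eivs",
    "write_site_eivs",
    "RunManifest",
]

logger = logging.getLogger(__name__)


class DataValidationError(ValueError):
    """Raised when an input file fails validation."""


# ---------------------------------------------------------------- rasters

def write_ascii_grid(
    path, array: np.ndarray, cell_size: float = 1.0,
    xllcorner: float = 0.0, yllcorner: float = 0.0,
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid."""
    a = np.asarray(array, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D array")
    rows, cols = a.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        out = np.where(np.isnan(a), nodata, a)
        for row in out:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header dict)."""
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and not _is_number(parts[0]):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    expect = (int(header.get("nrows", data.shape[0])),
              int(header.get("ncols", data.shape[1])))
    if data.shape != expect:
        raise DataValidationError(
            f"grid shape {data.shape} does not match header {expect}"
        )
    return data, header


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_landscape(bundle: LandscapeBundle, outdir) -> list[Path]:
    """Write every latent and mapped layer as an ASCII grid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for prefix, layers in (
        ("latent", bundle.latent_layers), ("mapped", bundle.mapped_layers)
    ):
        for name, layer in layers.items():
            p = outdir / f"{prefix}_{name}.asc"
            write_ascii_grid(p, layer, cell_size=bundle.cell_size)
            written.append(p)
    return written


# ----------------------------------------------------------------- tables

def write_plots_csv(plots: PlotCommunityMatrix, path) -> None:
    df = plots.plot_predictors.copy()
    df.insert(0, "y", plots.plot_xy[:, 0])
    df.insert(0, "x", plots.plot_xy[:, 1])
    if plots.group is not None:
        df.insert(2, "group", plots.group.to_numpy())
    df.to_csv(path, index=True, index_label="plot_id")


def write_presence_csv(plots: PlotCommunityMatrix, path) -> None:
    plots.presence.to_csv(path, index=True, index_label="plot_id")


def read_releve_table(path, predictors_path=None) -> PlotCommunityMatrix:
    """Read a relevé table (long or wide layout, auto-detected).

    Long layout has columns ``plot_id`` and ``species_id``; any other
    layout with a ``plot_id`` column and 0/1 data columns is treated as a
    wide presence matrix.  Duplicate (plot, species) occurrences collapse
    to a single presence with a warning.
    """
    df = pd.read_csv(path)
    # normalise only the structural columns; species names keep their case
    special = {"plot_id", "species_id", "group", "x", "y"}
    df.columns = [c.lower() if c.lower() in special else c
                  for c in df.columns]
    cols = list(df.columns)
    if "plot_id" not in cols:
        raise DataValidationError(
            "unknown relevé layout: expected a 'plot_id' column plus either "
            "a 'species_id' column (long) or per-species 0/1 columns (wide)"
        )
    if "species_id" in cols:
        dupes = df.duplicated(subset=["plot_id", "species_id"]).sum()
        if dupes:
            logger.warning(
                "%d duplicate (plot, species) rows collapsed", dupes
            )
        presence = (
            pd.crosstab(df["plot_id"], df["species_id"]).clip(upper=1)
        ).astype(np.int8)
    else:
        presence = df.set_index("plot_id")
        bad = ~presence.isin([0, 1]).to_numpy()
        if bad.any():
            raise DataValidationError(
                "wide relevé matrix contains values other than 0/1"
            )
        presence = presence.astype(np.int8)
    presence.index = presence.index.astype(str)
    presence.index.name = "plot_id"
    presence.columns = [str(c) for c in presence.columns]

    if predictors_path is not None:
        pred = pd.read_csv(predictors_path)
        pred.columns = [c.lower() for c in pred.columns]
        pred = pred.set_index("plot_id")
        pred.index = pred.index.astype(str)
        group = None
        if "group" in pred.columns:
            group = pred["group"].reindex(presence.index)
            pred = pred.drop(columns=["group"])
        xy = np.zeros((len(presence), 2), dtype=int)
        if {"x", "y"}.issubset(pred.columns):
            xy = (
                pred.reindex(presence.index)[["y", "x"]]
                .to_numpy(dtype=float).astype(int)
            )
            pred = pred.drop(columns=["x", "y"])
        pred = pred.reindex(presence.index)
    else:
        pred = pd.DataFrame(index=presence.index)
        group = None
        xy = np.zeros((len(presence), 2), dtype=int)
    return PlotCommunityMatrix(
        plot_ids=presence.index.to_numpy(),
        plot_xy=xy,
        presence=presence,
        plot_predictors=pred,
        group=group,
    )


def write_species_eivs(table: SpeciesEIVTable, path) -> None:
    table.values.to_csv(path, index=True, index_label="species_id")


def read_species_eivs(path, ordinal_range=(1, 5)) -> SpeciesEIVTable:
    """Species EIV CSV: species_id plus dimension columns; empty cells are
    missing; values outside the ordinal range are rejected with the
    offending row."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise DataValidationError("species EIV file needs a species_id column")
    df = df.set_index("species_id")
    df.index = df.index.astype(str)
    lo, hi = ordinal_range
    vals = df.to_numpy(dtype=float)
    bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataValidationError(
            f"EIV value {vals[i, j]} out of range [{lo}, {hi}] at data row "
            f"{i + 2} (species {df.index[i]!r}, column {df.columns[j]!r})"
        )
    return SpeciesEIVTable(values=df, ordinal_range=ordinal_range)


def write_site_eivs(matrix: SiteEIVMatrix, path) -> None:
    df = matrix.values.copy()
    for dim in matrix.n_contributing.columns:
        df[f"n_{dim}"] = matrix.n_contributing[dim]
    df.insert(0, "focal_species", matrix.focal_species or "")
    df.to_csv(path, index=True, index_label="plot_id")


# --------------------------------------------------------------- manifest

@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    master_seed: int
    config: dict
    stage_seeds: dict[str, int] = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)
    decisions: list[str] = field(default_factory=list)

    def add_input(self, name: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_hashes[name] = digest

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))
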