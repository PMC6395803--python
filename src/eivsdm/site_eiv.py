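"""Plot-level (site) ecological indicator values.

A site EIV is the unweighted arithmetic mean of the indicator values of
the species present at a plot.  When a site EIV is used as a predictor in
a distribution model for a focal species, that species is excluded from
the mean (leave-one-out) so the predictor carries no direct information
about the response.

The calculator vectorises the computation: base sums and counts over all
species are computed once, and each focal species' leave-one-out matrix is
obtained by subtracting its own contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EIV_CODE, PlotCommunityMatrix, VirtualSpecies

__all__ = [
    "SpeciesEIVTable",
    "SiteEIVMatrix",
    "SiteEIVCalculator",
    "compute_site_eivs",
    "EIV_DIMENSIONS",
]

logger = logging.getLogger(__name__)

#: canonical indicator dimensions (Landolt codes)
EIV_DIMENSIONS = ("T", "M", "L", "K", "R", "N")
#: accepted aliases on input ("F" is an older code for the moisture value)
EIV_ALIASES = {"F": "M"}


@dataclass
class SpeciesEIVTable:
    """Per-species ordinal indicator values; NaN marks a missing value."""

    values: pd.DataFrame  # index species_id, columns within EIV_DIMENSIONS
    ordinal_range: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dupes}")
        df = df.rename(columns=EIV_ALIASES)
        unknown = [c for c in df.columns if c not in EIV_DIMENSIONS]
        if unknown:
            raise ValueError(f"unknown EIV dimensions: {unknown}")
        lo, hi = self.ordinal_range
        vals = df.to_numpy(dtype=float)
        bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"EIV out of range [{lo}, {hi}]: species "
                f"{df.index[i]!r}, dimension {df.columns[j]!r}, "
                f"value {vals[i, j]}"
            )
        self.values = df.astype(float)

    @property
    def dimensions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_species_pool(cls, pool: list[VirtualSpecies]) -> "SpeciesEIVTable":
        """Build the table from virtual species (latent dimension names are
        translated to their indicator codes)."""
        rows = {}
        for sp in pool:
            rows[sp.species_id] = {
                EIV_CODE[d]: (np.nan if v is None else float(v))
                for d, v in sp.eiv.items()
                if d in EIV_CODE
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "species_id"
        df = df[[c for c in EIV_DIMENSIONS if c in df.columns]]
        return cls(values=df)


@dataclass
class SiteEIVMatrix:
    """Site EIVs per plot and dimension, with contributor counts.

    ``values`` is NaN exactly where ``n_contributing`` is zero.
    """

    values: pd.DataFrame  # plot_id x dimension
    n_contributing: pd.DataFrame  # plot_id x dimension, integer
    focal_species: str | None = None


class SiteEIVCalculator:
    """Computes site EIVs for any focal species from cached base sums."""

    def __init__(self, plots: PlotCommunityMatrix, eivs: SpeciesEIVTable):
        self.plots = plots
        self.eivs = eivs
        presence = plots.presence
        known = [s for s in presence.columns if s in eivs.values.index]
        missing = [s for s in presence.columns if s not in eivs.values.index]
        if missing:
            logger.warning(
                "%d species present in plots but absent from the EIV table "
                "are skipped: %s%s",
                len(missing),
                ", ".join(missing[:5]),
                "..." if len(missing) > 5 else "",
            )
        self._species = known
        self._presence = presence[known].to_numpy(dtype=float)
        eiv = eivs.values.loc[known].to_numpy(dtype=float)  # species x dim
        self._eiv_filled = np.nan_to_num(eiv, nan=0.0)
        self._eiv_mask = (~np.isnan(eiv)).astype(float)
        self._eiv_raw = eiv
        # plot x dim sums and contributor counts over ALL species
        self._base_sum = self._presence @ self._eiv_filled
        self._base_n = self._presence @ self._eiv_mask
        self._index = presence.index
        self._dims = list(eivs.values.columns)
        self._cache: dict[str | None, SiteEIVMatrix] = {}

    def site_eivs(self, focal_species: str | None = None) -> SiteEIVMatrix:
        if focal_species in self._cache:
            return self._cache[focal_species]
        s = self._base_sum
        n = self._base_n
        if focal_species is not None:
            known = (
                focal_species in self.plots.presence.columns
                or focal_species in self.eivs.values.index
            )
            if not known:
                raise KeyError(f"unknown focal species {focal_species!r}")
            if focal_species in self._species:
                j = self._species.index(focal_species)
                pres = self._presence[:, j:j + 1]  # plot x 1
                s = s - pres * self._eiv_filled[j]
                n = n - pres * self._eiv_mask[j]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(n > 0, s / np.where(n > 0, n, 1), np.nan)
        values = pd.DataFrame(vals, index=self._index, columns=self._dims)
        counts = pd.DataFrame(
            n.astype(int), index=self._index, columns=self._dims
        )
        result = SiteEIVMatrix(
            values=values, n_contributing=counts, focal_species=focal_species
        )
        self._cache[focal_species] = result
        return result


def compute_site_eivs(
    plots: PlotCommunityMatrix,
    eivs: SpeciesEIVTable,
    focal_species: str | None = None,
) -> SiteEIVMatrix:
    """Unweighted mean indicator value per plot and dimension, excluding
    the focal species and species with a missing value on that dimension."""
    return SiteEIVCalculator(plots, eivs).site_eivs(focal_species)
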