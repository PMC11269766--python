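"""Land-use map container for one landscape window."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from .rasters import Raster

__all__ = ["LandUseMap"]


@dataclass
class LandUseMap:
    """Categorical land-use raster plus linear elements and crop histories.

    ``landuse`` holds area-class codes (see :data:`linkerscape.config.AREA_CLASSES`)
    on a 10 m grid by default.  ``crop_years`` maps each crop type to a boolean
    stack of shape ``(n_years, nrows, ncols)`` marking presence of that crop in
    each year; ``lines`` maps each linear-element class to its polylines.
    ``patch_centroids`` are the forest-herb population centres (one per
    deciduous-forest study patch), keyed by patch id.
    """

    landuse: Raster
    crop_years: dict[str, np.ndarray]
    years: tuple[int, ...]
    lines: dict[str, list[LineString]] = field(default_factory=dict)
    patch_centroids: dict[str, tuple[float, float]] = field(default_factory=dict)
    window_id: str = "W0"
    #: precomputed whole-period dominance rasters (set when a map is read back
    #: from fixtures that store dominance instead of yearly stacks)
    dominance_cache: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.landuse.data.shape
        for crop, stack in self.crop_years.items():
            if stack.shape[1:] != shape:
                raise ValueError(f"crop stack {crop!r} does not share the land-use grid")
            if stack.shape[0] != len(self.years):
                raise ValueError(f"crop stack {crop!r} year dimension mismatch")

    def dominance(self, crop: str, period: tuple[int, int] | None = None) -> Raster:
        """Per-cell crop dominance: fraction of years the crop was present.

        A value of 1 means the crop was grown in every year of the period and
        0 means it was absent throughout.  ``period`` is an inclusive
        ``(first_year, last_year)`` range; default is all available years.
        """
        if crop in self.dominance_cache:
            if period is not None:
                raise ValueError(
                    "period selection unavailable: this map carries precomputed "
                    "whole-period dominance, not yearly crop stacks"
                )
            return self.dominance_cache[crop]
        stack = self.crop_years[crop]
        if period is None:
            sel = np.ones(len(self.years), dtype=bool)
        else:
            lo, hi = period
            sel = np.array([lo <= y <= hi for y in self.years])
            if not sel.any():
                raise ValueError(f"period {period} outside available years {self.years}")
        dom = stack[sel].mean(axis=0)
        return Raster(dom, self.landuse.x0, self.landuse.y0, self.landuse.cell)
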