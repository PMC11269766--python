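"""Readers and writers for fixture sets and result tables.

Fixture layout (as produced by :func:`linkerscape.synthetic.write_fixture_set`):

    <dir>/manifest.json
    <dir>/plants.csv, bees.csv        GenAlEx-style genotype tables
    <dir>/truth.json                  ground-truth record
    <dir>/W<k>/landuse.asc            categorical land-use grid (ESRI ASCII)
    <dir>/W<k>/dominance_<CROP>.asc   whole-period crop dominance grids
    <dir>/W<k>/vectors.geojson        linear elements + patch centroids
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, shape

from .config import CROP_CLASSES
from .genotypes import GenotypeTable
from .maps import LandUseMap
from .rasters import Raster
from .synthetic import TruthRecord

__all__ = ["read_genotypes", "read_landscape", "read_fixture_set", "read_truth"]


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a GenAlEx-style genotype CSV with schema validation."""
    return GenotypeTable.read_csv(path)


def read_landscape(window_dir: str | Path) -> LandUseMap:
    """Read one window directory back into a :class:`LandUseMap`.

    The returned map carries precomputed dominance rasters (the fixture
    format stores dominance, not yearly stacks), so ``dominance(crop)`` works
    but per-period selection does not.
    """
    window_dir = Path(window_dir)
    landuse = Raster.read_ascii(window_dir / "landuse.asc")
    landuse.data = landuse.data.astype(np.int16)
    dominance = {}
    for crop in CROP_CLASSES:
        p = window_dir / f"dominance_{crop}.asc"
        if p.exists():
            dominance[crop] = Raster.read_ascii(p)
    gj = json.loads((window_dir / "vectors.geojson").read_text())
    lines: dict[str, list[LineString]] = {}
    centroids: dict[str, tuple[float, float]] = {}
    for feat in gj["features"]:
        props = feat.get("properties", {})
        if "patch" in props:
            x, y = feat["geometry"]["coordinates"]
            centroids[props["patch"]] = (float(x), float(y))
        elif "class" in props:
            lines.setdefault(props["class"], []).append(shape(feat["geometry"]))
        else:
            raise ValueError(f"{window_dir}: vector feature lacks 'patch'/'class'")
    return LandUseMap(
        landuse=landuse, crop_years={}, years=(), lines=lines,
        patch_centroids=centroids, window_id=window_dir.name,
        dominance_cache=dominance,
    )


def read_truth(path: str | Path) -> TruthRecord:
    raw = json.loads(Path(path).read_text())
    return TruthRecord(
        true_nest_of_worker=raw["true_nest_of_worker"],
        nest_locations={k: tuple(v) for k, v in raw["nest_locations"].items()},
        true_clone_groups=raw["true_clone_groups"],
        injected_effects=raw["injected_effects"],
    )


def read_fixture_set(outdir: str | Path) -> dict:
    """Read a complete fixture directory; mirrors ``generate_study`` output."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    maps = [
        read_landscape(d) for d in sorted(outdir.glob("W*")) if d.is_dir()
    ]
    if not maps:
        raise FileNotFoundError(f"no window directories under {outdir}")
    return {
        "maps": maps,
        "plants": read_genotypes(outdir / "plants.csv"),
        "bees": read_genotypes(outdir / "bees.csv"),
        "truth": read_truth(outdir / "truth.json"),
        "manifest": manifest,
    }


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
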