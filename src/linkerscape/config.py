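"""Configuration objects and the land-use class inventory.

The class inventory mirrors a Central European agricultural mosaic: area-based
land-use classes mapped on a 10 m categorical grid, three crop types tracked as
per-year dominance rasters over arable land, and four classes of linear
landscape elements stored as polylines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

# ---- land-use inventory -------------------------------------------------

#: area-based classes present in the categorical raster (code -> name)
AREA_CLASSES: dict[int, str] = {
    1: "D_FOREST",      # deciduous forest (the herb's habitat)
    2: "C_FOREST",      # coniferous forest
    3: "GRASS",         # grassland in general
    4: "SEMNATGRASS",   # semi-natural grassland
    5: "SEMNATVEG",     # other semi-natural vegetation
    6: "ORCHARD",       # traditional orchards
    7: "SETTLE",        # settlement
    8: "ARABLE",        # arable land in general
    9: "WATER",         # open water
}

AREA_CLASS_CODES: dict[str, int] = {v: k for k, v in AREA_CLASSES.items()}

#: crop types measured as multi-year dominance rasters over arable cells
CROP_CLASSES: tuple[str, ...] = ("RAPESEED", "MAIZE", "CEREAL")

#: linear landscape element classes (polyline layers)
LINEAR_CLASSES: tuple[str, ...] = ("L_ROAD", "L_WATER", "L_WOOD", "L_FRINGE")

#: index metrics computed from the categorical raster
INDEX_METRICS: tuple[str, ...] = ("LANDHET", "EDGEDEN")

#: buffer radii (m) at the node level
NODE_RADII: tuple[float, ...] = (125.0, 250.0, 500.0, 1000.0, 2000.0)

#: width-to-length ratios of link-level strips
LINK_RATIOS: tuple[float, ...] = (1 / 7, 1 / 5, 1 / 3, 1 / 2, 2 / 3)

LINK_RATIO_LABELS: dict[float, str] = {
    1 / 7: "1to7",
    1 / 5: "1to5",
    1 / 3: "1to3",
    1 / 2: "1to2",
    2 / 3: "2to3",
}


def all_metric_names(include_water: bool = True) -> list[str]:
    """All landscape metric names available at both analysis levels."""
    area = [n for n in AREA_CLASSES.values() if include_water or n != "WATER"]
    return area + list(CROP_CLASSES) + list(LINEAR_CLASSES) + list(INDEX_METRICS)


# ---- synthetic-study configuration --------------------------------------

#: default mosaic composition per window (fractions of window area)
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "D_FOREST": 0.08,
    "C_FOREST": 0.05,
    "GRASS": 0.12,
    "SEMNATGRASS": 0.07,
    "SEMNATVEG": 0.04,
    "ORCHARD": 0.02,
    "SETTLE": 0.05,
    "ARABLE": 0.55,
    "WATER": 0.02,
}


@dataclass
class SynthConfig:
    """Study-design constants of the emulated field system.

    Defaults reproduce the sampling design: three 5 x 5 km landscape windows,
    six deciduous-forest patches per window, ~20 herb genotypes and 14-36
    bumblebee workers per patch, 6 herb loci / 8 bee loci with allele pools
    sized to give roughly 134 and 148 alleles in total, queen x single male
    (monogamous) nests placed on field-forest boundaries, and a distance-decay
    foraging kernel whose reach responds to configurable landscape effects.
    """

    n_windows: int = 3
    window_size_m: float = 5000.0
    cell_size_m: float = 10.0
    n_patches_per_window: int = 6
    patch_radius_m: float = 90.0
    patch_min_separation_m: float = 1100.0
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_nuclei: int = 900             # mosaic seeds (parcel grain ~2.8 ha)
    n_crop_years: int = 10
    crop_persistence: float = 0.75  # P(field grows its dominant crop in a year)

    n_plant_loci: int = 6
    n_bee_loci: int = 8
    plant_alleles_per_locus: tuple[int, ...] = (22, 23, 22, 22, 23, 22)   # sum 134
    bee_alleles_per_locus: tuple[int, ...] = (18, 19, 18, 19, 18, 19, 18, 19)  # 148
    dirichlet_concentration: float = 0.8

    plants_per_patch: int = 20
    workers_per_patch: tuple[int, int] = (14, 36)
    clonality_rate: float = 0.3
    pollen_donor_skew: float = 0.0   # 0 = panmixia; ->1 = few effective parents
    plant_coupling: float = 0.0      # pollen-migration coupling to worker sharing

    nest_density: float = 14.0       # nests per km of study-patch fringe
    kernel_scale_m: float = 600.0
    effect_maize: float = 0.0        # on log kernel scale, per SD of MAIZE2000
    effect_grass: float = 0.0        # per SD of SEMNATGRASS2000
    effect_landhet: float = 0.0      # per SD of LANDHET125
    genotyping_error: float = 0.0

    rng_seed: int = 20240725

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(AREA_CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown land-use classes: {sorted(unknown)}")
        for name in (
            "n_windows", "n_patches_per_window", "n_plant_loci", "n_bee_loci",
            "plants_per_patch", "n_crop_years", "n_nuclei",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.workers_per_patch
        if not (0 < lo <= hi):
            raise ValueError("workers_per_patch range must be 0 < lo <= hi")
        for name in ("clonality_rate", "genotyping_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.pollen_donor_skew < 1.0:
            raise ValueError("pollen_donor_skew must be in [0, 1)")


#: magnitude used when a single landscape effect is injected in recovery
#: experiments (on the log foraging-range scale, per SD of the metric)
SINGLE_EFFECT_SIZE = 0.8

#: preset producing heterozygote excess via few effective pollen donors
HET_EXCESS_PRESET = {"pollen_donor_skew": 0.9, "clonality_rate": 0.35}

#: the full synthetic study treatment: maize-rich surroundings and local
#: heterogeneity lengthen worker foraging trips (grassland is left at zero
#: here because grass and maize covers are positively coupled through
#: compositional closure in these mosaics and opposite-signed effects would
#: cancel), a moderate baseline foraging range so among-patch sharing is not
#: saturated, heterozygote excess on the herb side, and pollen migration
#: coupled to worker nest sharing
STUDY_PRESET = {
    "effect_maize": 0.6,
    "effect_landhet": 0.35,
    "kernel_scale_m": 350.0,
    "plant_coupling": 0.8,
    **HET_EXCESS_PRESET,
}


# ---- pipeline configuration ---------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and scale sets of the four-step selection pipeline."""

    node_radii: tuple[float, ...] = NODE_RADII
    link_ratios: tuple[float, ...] = LINK_RATIOS
    alpha_preselect: float = 0.15       # LRT preselection level
    collinearity_r: float = 0.7         # |Pearson r| exclusion threshold
    delta_aicc: float = 2.0             # best-model band
    percentile_criterion: float = 0.95  # Step-4 pass level
    consensus_threshold: float = 0.8    # full-sib pair support in both runs
    max_terms_node: int = 2             # distinct metrics per node-level model
    max_terms_link: int = 4
    sibship_restarts: int = 20          # restarts per reconstruction run
    dominance_period: tuple[int, int] | None = None  # (first, last) crop year
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha_preselect < 1:
            raise ValueError("alpha_preselect must be in (0, 1)")
        if not 0 < self.collinearity_r <= 1:
            raise ValueError("collinearity_r must be in (0, 1]")
        if self.delta_aicc <= 0:
            raise ValueError("delta_aicc must be positive")
        if not 0 < self.percentile_criterion <= 1:
            raise ValueError("percentile_criterion must be in (0, 1]")
        if not 0 <= self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in [0, 1]")


def load_config(path: str | Path) -> tuple[SynthConfig, PipelineConfig]:
    """Read a YAML file with optional ``synth:`` and ``pipeline:`` sections."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    synth = SynthConfig(**_coerce(raw.get("synth", {}), SynthConfig))
    pipe = PipelineConfig(**_coerce(raw.get("pipeline", {}), PipelineConfig))
    synth.validate()
    pipe.validate()
    return synth, pipe


def dump_config(synth: SynthConfig, pipe: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"synth": asdict(synth), "pipeline": asdict(pipe)})
    )


def _coerce(section: dict[str, Any], cls: type) -> dict[str, Any]:
    fields = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    out = dict(section)
    for key in ("workers_per_patch", "plant_alleles_per_locus",
                "bee_alleles_per_locus", "node_radii", "link_ratios",
                "dominance_period"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out
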