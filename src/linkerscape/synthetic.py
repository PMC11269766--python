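"""Synthetic study system: landscape windows, genotypes, nests and movements.

Emulates the field design end to end with known ground truth so every
downstream stage is testable: three 5 x 5 km landscape windows on a 10 m
categorical grid with six deciduous-forest study patches each, partially
clonal herb populations (~20 genotypes per patch, 6 loci) whose pollen-donor
pool size controls heterozygote excess, and monogamous bumblebee nests
(queen x single haploid male) placed on the study-patch fringes whose
workers forage under a distance-decay kernel.  Configurable landscape
effects rescale each nest's foraging range, so maize-rich or heterogeneous
surroundings lengthen foraging trips and raise among-patch nest sharing --
the mechanism the pipeline is meant to recover.

The mosaic generator is a seeded nucleation + region-growing scheme: nuclei
are scattered uniformly, assigned classes by largest-remainder allocation of
the target proportions, and every cell joins its nearest nucleus, which gives
contiguous patches whose realized cover tracks the targets closely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, mapping

from .config import (
    AREA_CLASS_CODES,
    CROP_CLASSES,
    LINEAR_CLASSES,
    SynthConfig,
)
from .genotypes import GenotypeTable
from .landscape import node_metrics
from .maps import LandUseMap
from .rasters import Raster

__all__ = [
    "TruthRecord", "generate_landscape", "generate_plant_populations",
    "generate_nests_and_workers", "generate_study", "write_fixture_set",
]


@dataclass
class TruthRecord:
    """Ground truth of one synthetic window (or study) for recovery tests."""

    true_nest_of_worker: dict[str, str] = field(default_factory=dict)
    nest_locations: dict[str, tuple[float, float]] = field(default_factory=dict)
    true_clone_groups: dict[str, str] = field(default_factory=dict)  # ramet -> genet
    injected_effects: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "TruthRecord") -> None:
        self.true_nest_of_worker.update(other.true_nest_of_worker)
        self.nest_locations.update(other.nest_locations)
        self.true_clone_groups.update(other.true_clone_groups)
        self.injected_effects.update(other.injected_effects)


# ---- landscape -----------------------------------------------------------

def _allocate_nuclei_classes(proportions: dict[str, float], n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of nucleus classes to target proportions."""
    names = sorted(proportions)
    quotas = np.array([proportions[c] * n for c in names])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:remainder]] += 1
    codes = np.repeat([AREA_CLASS_CODES[c] for c in names], counts)
    rng.shuffle(codes)
    return codes


def _place_patches(cfg: SynthConfig, rng: np.random.Generator,
                   max_tries: int = 2000) -> list[tuple[float, float]]:
    """Patch centroids with a minimum separation, kept off the window edge."""
    margin = cfg.patch_radius_m + 2 * cfg.cell_size_m
    lo, hi = margin, cfg.window_size_m - margin
    centres: list[tuple[float, float]] = []
    for _ in range(max_tries):
        if len(centres) == cfg.n_patches_per_window:
            return centres
        cand = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        if all(np.hypot(cand[0] - x, cand[1] - y) >= cfg.patch_min_separation_m
               for x, y in centres):
            centres.append(cand)
    raise RuntimeError(
        f"could not place {cfg.n_patches_per_window} patches with separation "
        f"{cfg.patch_min_separation_m} m in a {cfg.window_size_m} m window"
    )


def _random_lines(cfg: SynthConfig, rng: np.random.Generator
                  ) -> dict[str, list[LineString]]:
    """Simple linear-element layers: chords, meanders and short segments."""
    W = cfg.window_size_m
    lines: dict[str, list[LineString]] = {c: [] for c in LINEAR_CLASSES}
    for _ in range(4):  # roads: straight chords across the window
        if rng.random() < 0.5:
            x = rng.uniform(0.1 * W, 0.9 * W)
            lines["L_ROAD"].append(LineString([(x, 0), (x + rng.uniform(-W / 5, W / 5), W)]))
        else:
            y = rng.uniform(0.1 * W, 0.9 * W)
            lines["L_ROAD"].append(LineString([(0, y), (W, y + rng.uniform(-W / 5, W / 5))]))
    for _ in range(2):  # watercourses: random-walk meanders
        pts = [np.array([rng.uniform(0, W), 0.0])]
        heading = np.pi / 2 + rng.uniform(-0.4, 0.4)
        while 0 <= pts[-1][0] <= W and pts[-1][1] <= W:
            heading += rng.uniform(-0.5, 0.5)
            pts.append(pts[-1] + 250.0 * np.array([np.cos(heading), np.sin(heading)]))
        if len(pts) > 1:
            lines["L_WATER"].append(LineString([tuple(p) for p in pts]))
    for _ in range(30):  # woody lines: short hedgerow segments
        x, y = rng.uniform(0, W, size=2)
        ang = rng.uniform(0, 2 * np.pi)
        L = rng.uniform(100, 400)
        lines["L_WOOD"].append(LineString([
            (x, y), (x + L * np.cos(ang), y + L * np.sin(ang)),
        ]))
    return lines


def _forest_fringes(landuse: Raster) -> list[LineString]:
    """Forest-fringe polylines: cell edges between deciduous forest and open land."""
    forest = landuse.data == AREA_CLASS_CODES["D_FOREST"]
    cell = landuse.cell
    nrows = landuse.nrows
    segs: list[LineString] = []
    diff_h = forest[:, :-1] != forest[:, 1:]
    for r, c in zip(*np.nonzero(diff_h)):
        x = landuse.x0 + (c + 1) * cell
        y = landuse.y0 + (nrows - r - 1) * cell
        segs.append(LineString([(x, y), (x, y + cell)]))
    diff_v = forest[:-1, :] != forest[1:, :]
    for r, c in zip(*np.nonzero(diff_v)):
        x = landuse.x0 + c * cell
        y = landuse.y0 + (nrows - r - 1) * cell
        segs.append(LineString([(x, y), (x + cell, y)]))
    return segs


def _crop_year_stacks(cfg: SynthConfig, landuse: Raster, rng: np.random.Generator
                      ) -> tuple[dict[str, np.ndarray], tuple[int, ...]]:
    """Per-crop yearly presence on arable fields with rotational persistence."""
    arable = landuse.data == AREA_CLASS_CODES["ARABLE"]
    years = tuple(range(2008, 2008 + cfg.n_crop_years))
    shape = (len(years),) + landuse.data.shape
    stacks = {crop: np.zeros(shape, dtype=bool) for crop in CROP_CLASSES}
    if not arable.any():
        return stacks, years
    # partition arable cells into fields via nearest of ~60 field nuclei
    rows, cols = np.nonzero(arable)
    n_fields = min(60, len(rows))
    pick = rng.choice(len(rows), size=n_fields, replace=False)
    tree = cKDTree(np.column_stack([rows[pick], cols[pick]]))
    _, fid = tree.query(np.column_stack([rows, cols]))
    crops = list(CROP_CLASSES) + ["OTHER"]
    # dominant crop per field; MAIZE-heavy mix typical of fodder-maize regions
    dom_p = np.array([0.2, 0.35, 0.3, 0.15])
    dominant = rng.choice(len(crops), size=n_fields, p=dom_p)
    for y in range(len(years)):
        grown = np.where(
            rng.random(n_fields) < cfg.crop_persistence,
            dominant,
            rng.integers(0, len(crops), size=n_fields),
        )
        for ci, crop in enumerate(CROP_CLASSES):
            sel = grown[fid] == ci
            stacks[crop][y, rows[sel], cols[sel]] = True
    return stacks, years


def generate_landscape(cfg: SynthConfig, window_index: int) -> LandUseMap:
    """One landscape window: mosaic raster, patches, lines, crop histories."""
    cfg.validate()
    rng = np.random.default_rng([cfg.rng_seed, 11, window_index])
    n = int(round(cfg.window_size_m / cfg.cell_size_m))
    # nucleation + region growing (nearest-nucleus assignment)
    nuc_rc = rng.uniform(0, n, size=(cfg.n_nuclei, 2))
    nuc_codes = _allocate_nuclei_classes(cfg.class_proportions, cfg.n_nuclei, rng)
    rr, cc = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5, indexing="ij")
    tree = cKDTree(nuc_rc)
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    data = nuc_codes[nearest].reshape(n, n).astype(np.int16)
    landuse = Raster(data, 0.0, 0.0, cfg.cell_size_m)
    # force circular deciduous-forest study patches
    centres = _place_patches(cfg, rng)
    xs = (cc) * cfg.cell_size_m
    ys = (n - rr) * cfg.cell_size_m
    for (px, py) in centres:
        inside = (xs - px) ** 2 + (ys - py) ** 2 <= cfg.patch_radius_m ** 2
        data[inside] = AREA_CLASS_CODES["D_FOREST"]
    crop_years, years = _crop_year_stacks(cfg, landuse, rng)
    lines = _random_lines(cfg, rng)
    lines["L_FRINGE"] = _forest_fringes(landuse)
    wid = f"W{window_index}"
    patch_ids = {f"{wid}P{k}": c for k, c in enumerate(centres)}
    return LandUseMap(
        landuse=landuse, crop_years=crop_years, years=years, lines=lines,
        patch_centroids=patch_ids, window_id=wid,
    )


# ---- allele pools --------------------------------------------------------

def _window_freqs(alleles_per_locus: tuple[int, ...], concentration: float,
                  rng: np.random.Generator) -> list[np.ndarray]:
    return [
        rng.dirichlet(np.full(k, concentration))
        for k in alleles_per_locus
    ]


def _draw_genotype(freqs: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    L = len(freqs)
    g = np.zeros((L, 2), dtype=np.int64)
    for l, f in enumerate(freqs):
        g[l] = rng.choice(len(f), size=2, p=f) + 1  # allele labels are 1-based
    return g


def _apply_error(g: np.ndarray, freqs: list[np.ndarray], err: float,
                 rng: np.random.Generator) -> np.ndarray:
    if err <= 0:
        return g
    out = g.copy()
    for l, f in enumerate(freqs):
        for a in range(2):
            if rng.random() < err:
                out[l, a] = rng.integers(1, len(f) + 1)
    return out


# ---- plants --------------------------------------------------------------

def generate_plant_populations(
    lum: LandUseMap, cfg: SynthConfig,
    freqs: list[np.ndarray] | None = None,
    migration: np.ndarray | None = None,
) -> tuple[GenotypeTable, TruthRecord]:
    """Partially clonal herb populations for every patch of one window.

    Each patch holds a genet pool whose offspring are produced by a local
    mother pool and a pollen-donor pool; ``pollen_donor_skew`` shrinks both
    pools, and few effective parents produce the heterozygote excess
    (negative F) typical of small clonal populations.  ``clonality_rate`` is
    the fraction of sampled ramets that repeat an already-sampled genet.
    With a migration matrix (patch x patch, rows summing to 1) pollen donors
    are drawn from other patches' parent pools at the given rates.
    """
    rng = np.random.default_rng([cfg.rng_seed, 23, int(lum.window_id[1:])])
    if freqs is None:
        freqs = _window_freqs(cfg.plant_alleles_per_locus,
                              cfg.dirichlet_concentration, rng)
    patches = sorted(lum.patch_centroids)
    n_parents = max(2, int(round((1.0 - cfg.pollen_donor_skew) * 2 * cfg.plants_per_patch)))
    parent_pools = {
        p: [_draw_genotype(freqs, rng) for _ in range(n_parents)] for p in patches
    }
    ids, pops, wins, genos = [], [], [], []
    truth = TruthRecord(injected_effects={"pollen_donor_skew": cfg.pollen_donor_skew,
                                          "clonality_rate": cfg.clonality_rate})

    def _offspring(patch_i: int) -> np.ndarray:
        pool = parent_pools[patches[patch_i]]
        mi = rng.integers(len(pool))
        mother = pool[mi]
        if migration is not None and rng.random() > migration[patch_i, patch_i]:
            row = migration[patch_i].copy()
            row[patch_i] = 0.0
            row = row / row.sum()
            donor_pool = parent_pools[patches[rng.choice(len(patches), p=row)]]
            father = donor_pool[rng.integers(len(donor_pool))]
        elif len(pool) > 1:
            # strictly outcrossing: the pollen donor is never the mother
            fi = rng.integers(len(pool) - 1)
            father = pool[fi if fi < mi else fi + 1]
        else:
            father = pool[0]
        child = np.zeros_like(mother)
        for l in range(child.shape[0]):
            child[l, 0] = mother[l, rng.integers(2)]
            child[l, 1] = father[l, rng.integers(2)]
        return child

    for pi, patch in enumerate(patches):
        genets: list[tuple[str, np.ndarray]] = []
        for k in range(cfg.plants_per_patch):
            rid = f"{patch}_pl{k}"
            if genets and rng.random() < cfg.clonality_rate:
                gid, g = genets[rng.integers(len(genets))]
            else:
                g = _offspring(pi)
                gid = rid
                genets.append((gid, g))
            truth.true_clone_groups[rid] = gid
            ids.append(rid)
            pops.append(patch)
            wins.append(lum.window_id)
            genos.append(_apply_error(g, freqs, cfg.genotyping_error, rng))
    table = GenotypeTable(
        np.array(ids), np.array(pops), np.array(wins), np.stack(genos),
        tuple(f"PL{l+1}" for l in range(cfg.n_plant_loci)),
    )
    return table, truth


# ---- bees ----------------------------------------------------------------

def _boundary_points(lum: LandUseMap) -> np.ndarray:
    """Cell-centre coordinates of forest cells on the field-forest boundary."""
    landuse = lum.landuse
    forest = landuse.data == AREA_CLASS_CODES["D_FOREST"]
    pad = np.pad(forest, 1, constant_values=False)
    boundary = forest & ~(
        pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    )
    rows, cols = np.nonzero(boundary)
    xs = landuse.x0 + (cols + 0.5) * landuse.cell
    ys = landuse.y0 + (landuse.nrows - rows - 0.5) * landuse.cell
    return np.column_stack([xs, ys])


def patch_effect_scores(lum: LandUseMap, cfg: SynthConfig) -> dict[str, float]:
    """Per patch, the linear predictor of the injected landscape effects.

    Uses the same metrics the pipeline estimates: maize dominance and
    semi-natural grassland cover in the 2000 m buffer and landscape
    heterogeneity in the 125 m buffer, standardized across the window's
    patches.
    """
    table = node_metrics(
        lum, lum.patch_centroids, radii=(125.0, 2000.0),
        metrics=("MAIZE", "SEMNATGRASS", "LANDHET"),
    )
    wide = table.pivot_table(index="unit", columns=["metric", "scale"], values="value")

    def z(col) -> np.ndarray:
        x = wide[col].to_numpy(dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    score = (
        cfg.effect_maize * z(("MAIZE", "2000"))
        + cfg.effect_grass * z(("SEMNATGRASS", "2000"))
        + cfg.effect_landhet * z(("LANDHET", "125"))
    )
    return dict(zip(wide.index, score))


def generate_nests_and_workers(
    lum: LandUseMap, cfg: SynthConfig,
    freqs: list[np.ndarray] | None = None,
) -> tuple[GenotypeTable, TruthRecord]:
    """Monogamous nests on field-forest boundaries and the workers caught per patch.

    Nests are placed at ``nest_density`` per km of boundary; each is a queen
    plus a single male drawn from the window's allele frequencies.  A patch
    catches workers from nest i with probability proportional to
    exp(-d_i / kernel_i), where the kernel scale of nest i is
    kernel_scale_m x exp(effect score of the landscape around the nest,
    evaluated at its nearest forest patch).  Positive effects (e.g.
    maize-rich surroundings offering little forage) lengthen that nest's
    foraging trips, so its workers turn up in several patches and raise
    among-patch nest sharing exactly where the effect metric is high.
    """
    widx = int(lum.window_id[1:])
    rng = np.random.default_rng([cfg.rng_seed, 37, widx])
    if freqs is None:
        freqs = _window_freqs(cfg.bee_alleles_per_locus,
                              cfg.dirichlet_concentration, rng)
    boundary = _boundary_points(lum)
    if len(boundary) == 0:
        raise RuntimeError("no field-forest boundary cells in the window")
    # nests sit on the fringes of the study patches (queens favour the
    # boundaries of the forest patches the workers forage in); using the
    # identical-geometry fringes keeps the local nest pool balanced across
    # patches so capture patterns respond to foraging range, not pool size
    centres_arr = np.array([lum.patch_centroids[p] for p in sorted(lum.patch_centroids)])
    d_to_patch = np.min(np.hypot(
        boundary[:, None, 0] - centres_arr[None, :, 0],
        boundary[:, None, 1] - centres_arr[None, :, 1],
    ), axis=1)
    fringe = boundary[d_to_patch <= cfg.patch_radius_m + 2 * lum.landuse.cell]
    if len(fringe) > 0:
        boundary = fringe
    boundary_km = len(boundary) * lum.landuse.cell / 1000.0
    n_nests = max(cfg.n_patches_per_window, int(round(cfg.nest_density * boundary_km)))
    nest_xy = boundary[rng.choice(len(boundary), size=n_nests, replace=True)]
    queens = [_draw_genotype(freqs, rng) for _ in range(n_nests)]
    males = [np.repeat(_draw_genotype(freqs, rng)[:, :1], 2, axis=1)
             for _ in range(n_nests)]  # haploid male: one allele per locus

    scores = patch_effect_scores(lum, cfg)
    patches = sorted(lum.patch_centroids)
    centres = np.array([lum.patch_centroids[p] for p in patches])
    # each nest forages at the kernel scale set by its surrounding landscape,
    # proxied by the effect score of its nearest study patch
    d_nest_patch = np.hypot(
        nest_xy[:, None, 0] - centres[None, :, 0],
        nest_xy[:, None, 1] - centres[None, :, 1],
    )
    nearest = d_nest_patch.argmin(axis=1)
    score_arr = np.array([scores[p] for p in patches])
    nest_kernel = cfg.kernel_scale_m * np.exp(score_arr[nearest])
    ids, pops, wins, genos = [], [], [], []
    truth = TruthRecord(injected_effects={
        "effect_maize": cfg.effect_maize, "effect_grass": cfg.effect_grass,
        "effect_landhet": cfg.effect_landhet,
    })
    for k in range(n_nests):
        truth.nest_locations[f"{lum.window_id}N{k}"] = tuple(nest_xy[k])
    lo, hi = cfg.workers_per_patch
    for pi, patch in enumerate(patches):
        d = d_nest_patch[:, pi]
        if cfg.kernel_scale_m <= 1e-9:
            w = (d == d.min()).astype(float)
        else:
            with np.errstate(over="ignore"):
                w = np.exp(-d / np.maximum(nest_kernel, 1e-9))
        w = w / w.sum()
        n_workers = int(rng.integers(lo, hi + 1))
        nest_of = rng.choice(n_nests, size=n_workers, p=w)
        for j, nk in enumerate(nest_of):
            wid_label = f"{patch}_bb{j}"
            q, m = queens[nk], males[nk]
            child = np.zeros_like(q)
            for l in range(child.shape[0]):
                child[l, 0] = q[l, rng.integers(2)]
                child[l, 1] = m[l, 0]
            child = _apply_error(child, freqs, cfg.genotyping_error, rng)
            ids.append(wid_label)
            pops.append(patch)
            wins.append(lum.window_id)
            genos.append(child)
            truth.true_nest_of_worker[wid_label] = f"{lum.window_id}N{nk}"
    table = GenotypeTable(
        np.array(ids), np.array(pops), np.array(wins), np.stack(genos),
        tuple(f"BB{l+1}" for l in range(cfg.n_bee_loci)),
        years=np.full(len(ids), 2018),
    )
    return table, truth


# ---- whole study ---------------------------------------------------------

def _sharing_migration(truth: TruthRecord, patches: list[str],
                       coupling: float) -> np.ndarray | None:
    """Island-model pollen-migration matrix proportional to shared-nest counts."""
    if coupling <= 0:
        return None
    P = len(patches)
    pidx = {p: i for i, p in enumerate(patches)}
    nest_patches: dict[str, set[int]] = {}
    for wkr, nest in truth.true_nest_of_worker.items():
        patch = wkr.rsplit("_bb", 1)[0]
        nest_patches.setdefault(nest, set()).add(pidx[patch])
    share = np.zeros((P, P))
    for ps in nest_patches.values():
        for a in ps:
            for b in ps:
                if a != b:
                    share[a, b] += 1.0
    mig = np.eye(P)
    row_tot = share.sum(axis=1)
    for i in range(P):
        if row_tot[i] > 0:
            off = coupling * min(1.0, row_tot[i] / (row_tot.max() + 1e-12))
            mig[i, :] = off * share[i] / row_tot[i]
            mig[i, i] = 1.0 - off
    return mig


def generate_study(cfg: SynthConfig) -> dict:
    """All windows: maps, plant and bee genotype tables, merged truth."""
    cfg.validate()
    maps, plant_tables, bee_tables = [], [], []
    truth = TruthRecord()
    for w in range(cfg.n_windows):
        lum = generate_landscape(cfg, w)
        bees, bee_truth = generate_nests_and_workers(lum, cfg)
        truth.merge(bee_truth)
        patches = sorted(lum.patch_centroids)
        migration = _sharing_migration(bee_truth, patches, cfg.plant_coupling)
        plants, plant_truth = generate_plant_populations(lum, cfg, migration=migration)
        truth.merge(plant_truth)
        maps.append(lum)
        plant_tables.append(plants)
        bee_tables.append(bees)
    return {
        "maps": maps,
        "plants": _concat_tables(plant_tables),
        "bees": _concat_tables(bee_tables),
        "truth": truth,
        "config": cfg,
    }


def _concat_tables(tables: list[GenotypeTable]) -> GenotypeTable:
    return GenotypeTable(
        np.concatenate([t.ids for t in tables]),
        np.concatenate([t.pops for t in tables]),
        np.concatenate([t.windows for t in tables]),
        np.concatenate([t.alleles for t in tables]),
        tables[0].locus_names,
        None if tables[0].years is None
        else np.concatenate([t.years for t in tables]),
    )


# ---- fixtures ------------------------------------------------------------

def write_fixture_set(outdir: str | Path, cfg: SynthConfig) -> dict:
    """Write a complete study to disk; returns the manifest (also saved).

    Rasters go out as ESRI ASCII grids, vector layers as GeoJSON, genotype
    tables as GenAlEx-style CSV and the truth record + manifest as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_study(cfg)
    paths: list[str] = []

    def _rel(p: Path) -> str:
        paths.append(str(p.relative_to(outdir)))
        return str(p)

    for lum in study["maps"]:
        wdir = outdir / lum.window_id
        wdir.mkdir(exist_ok=True)
        lum.landuse.write_ascii(_rel(wdir / "landuse.asc"), fmt="%d")
        for crop, stack in lum.crop_years.items():
            dom = lum.dominance(crop)
            dom.write_ascii(_rel(wdir / f"dominance_{crop}.asc"), fmt="%.3f")
        features = []
        for cls, lines in lum.lines.items():
            for line in lines:
                features.append({
                    "type": "Feature",
                    "properties": {"class": cls},
                    "geometry": mapping(line),
                })
        for pid, (x, y) in lum.patch_centroids.items():
            features.append({
                "type": "Feature",
                "properties": {"patch": pid},
                "geometry": {"type": "Point", "coordinates": [x, y]},
            })
        Path(_rel(wdir / "vectors.geojson")).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
    study["plants"].write_csv(_rel(outdir / "plants.csv"))
    study["bees"].write_csv(_rel(outdir / "bees.csv"))
    truth = study["truth"]
    Path(_rel(outdir / "truth.json")).write_text(json.dumps({
        "true_nest_of_worker": truth.true_nest_of_worker,
        "nest_locations": {k: list(v) for k, v in truth.nest_locations.items()},
        "true_clone_groups": truth.true_clone_groups,
        "injected_effects": truth.injected_effects,
    }, indent=1, sort_keys=True))
    manifest = {"seed": cfg.rng_seed, "n_files": len(paths), "files": sorted(paths)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
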