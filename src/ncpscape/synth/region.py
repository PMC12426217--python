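"""Synthetic study-region generator.

Builds a multi-timestep landscape (land cover, population, protection,
threats, climate) over a Voronoi partition of municipalities, with planted
archetype structure: each municipality follows one archetype's land-cover
trajectory (plus noise), so downstream trend profiles separate by archetype.

All randomness flows from ``RegionSpec.seed`` through named substreams, so
individual layers are reproducible even when others change.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from ..types import (
    LAND_COVER_CLASSES,
    LC_CODE,
    EconTables,
    LandscapeStack,
    RegionSpec,
)
from .archetypes import N_CLASSES, ArchetypeTemplate, make_templates

_SET = LC_CODE["settlement"]
_WAT = LC_CODE["water"]

#: Spatial allocation priority: classes earlier in the list claim the most
#: suitable remaining pixels first. Water first (static patches), settlement
#: second (nested growth = irreversible urbanization), the last class fills
#: whatever remains.
_ALLOCATION_ORDER = (
    "water",
    "settlement",
    "park_public",
    "horticulture",
    "cropland",
    "forest",
    "meadow_pasture",
    "other",
)

_NATURAL_CLASSES = ("forest", "meadow_pasture", "water", "park_public")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, seed-derived random substream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


def planted_labels(spec: RegionSpec) -> np.ndarray:
    """Ground-truth municipality -> archetype assignment.

    Counts are as balanced as ``n_municipalities`` allows; which municipality
    gets which archetype is a seed-dependent permutation.
    """
    rng = substream(spec.seed, "labels")
    perm = rng.permutation(spec.n_municipalities)
    labels = np.empty(spec.n_municipalities, dtype=int)
    labels[perm] = np.arange(spec.n_municipalities) % spec.n_archetypes
    return labels


def _voronoi_zones(spec: RegionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Partition the grid into municipality zones by nearest seed point.

    Returns (zones raster, distance-to-own-seed raster in pixel units).
    Every pixel belongs to exactly one zone and every zone contains at least
    its own seed pixel.
    """
    h, w = spec.grid_shape
    rng = substream(spec.seed, "zones")
    flat = rng.choice(h * w, size=spec.n_municipalities, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, (h, w))).astype(float)
    rows, cols = np.mgrid[0:h, 0:w]
    pixels = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    dist, zone = cKDTree(seeds).query(pixels)
    return zone.reshape(h, w).astype(np.int32), dist.reshape(h, w)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` pixels to class fractions."""
    raw = fractions / fractions.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _municipality_fractions(
    spec: RegionSpec,
    templates: list[ArchetypeTemplate],
    labels: np.ndarray,
) -> np.ndarray:
    """Class-fraction trajectory per municipality, shape (M, T, C).

    Municipality composition = archetype trajectory, blended toward the
    regional mean by ``archetype_mixing``, with multiplicative lognormal
    noise. Most of the noise budget goes to a municipality-level factor
    applied at every timestep (composition heterogeneity); the per-timestep
    jitter is an order of magnitude weaker so that a municipality keeps its
    archetype's temporal signature — archetypes are planted as trend
    patterns, not just as compositions.
    """
    traj = np.stack(
        [tpl.fractions_over_time(spec.n_timesteps) for tpl in templates]
    )  # (A, T, C)
    regional = traj.mean(axis=0)
    rng = substream(spec.seed, "fractions")
    out = np.empty((spec.n_municipalities, spec.n_timesteps, N_CLASSES))
    for m in range(spec.n_municipalities):
        base = (1 - spec.archetype_mixing) * traj[labels[m]] + (
            spec.archetype_mixing * regional
        )
        fixed = np.exp(spec.noise_sd * rng.standard_normal(N_CLASSES))
        jitter = np.exp(
            0.1 * spec.noise_sd
            * rng.standard_normal((spec.n_timesteps, N_CLASSES))
        )
        f = base * fixed[None, :] * jitter
        out[m] = f / f.sum(axis=1, keepdims=True)
    return out


def _class_counts(fractions_mt: np.ndarray, n_pixels: int) -> np.ndarray:
    """Per-timestep integer class counts for one zone, settlement monotone.

    Urbanization is treated as irreversible: the settlement count never
    decreases between timesteps; the surplus is taken from the largest
    non-settlement, non-water class.
    """
    n_t = fractions_mt.shape[0]
    counts = np.empty((n_t, N_CLASSES), dtype=int)
    for t in range(n_t):
        counts[t] = _largest_remainder(fractions_mt[t], n_pixels)
    for t in range(1, n_t):
        deficit = counts[t - 1, _SET] - counts[t, _SET]
        while deficit > 0:
            donors = [
                c for c in range(N_CLASSES)
                if c not in (_SET, _WAT) and counts[t, c] > 0
            ]
            if not donors:
                break
            donor = max(donors, key=lambda c: counts[t, c])
            take = min(deficit, counts[t, donor])
            counts[t, donor] -= take
            counts[t, _SET] += take
            deficit -= take
    return counts


def _suitability_fields(
    spec: RegionSpec, seed_distance: np.ndarray
) -> np.ndarray:
    """Static per-class suitability surfaces, shape (C, H, W).

    Smooth Gaussian random fields; settlement suitability additionally rises
    toward each municipality's seed point (urban cores), and the water field
    is smoother so lakes come out contiguous.
    """
    h, w = spec.grid_shape
    rng = substream(spec.seed, "suitability")
    fields = np.empty((N_CLASSES, h, w))
    for c, name in enumerate(LAND_COVER_CLASSES):
        sigma = 6.0 if name == "water" else 4.0
        f = gaussian_filter(rng.standard_normal((h, w)), sigma)
        f = (f - f.mean()) / (f.std() + 1e-12)
        fields[c] = f
    centrality = 1.0 - seed_distance / (seed_distance.max() + 1e-12)
    fields[_SET] += 1.5 * centrality
    return fields


def _allocate_land_cover(
    spec: RegionSpec,
    zones: np.ndarray,
    fractions: np.ndarray,
    suitability: np.ndarray,
) -> np.ndarray:
    """Turn per-zone class-fraction trajectories into categorical rasters.

    Within each zone, classes claim pixels in a fixed priority order, each
    taking its most suitable remaining pixels. Suitability is static in time,
    so change between timesteps is spatially clustered around existing
    patches and settlement growth is nested.
    """
    h, w = spec.grid_shape
    n_t = spec.n_timesteps
    lc = np.empty((n_t, h, w), dtype=np.int8)
    zone_flat = zones.ravel()
    suit_flat = suitability.reshape(N_CLASSES, -1)
    order_codes = [LC_CODE[name] for name in _ALLOCATION_ORDER]
    for m in range(spec.n_municipalities):
        idx = np.flatnonzero(zone_flat == m)
        counts = _class_counts(fractions[m], idx.size)
        for t in range(n_t):
            remaining = idx
            for c in order_codes[:-1]:
                k = counts[t, c]
                if k == 0:
                    continue
                if k >= remaining.size:
                    chosen = remaining
                else:
                    part = np.argpartition(-suit_flat[c, remaining], k - 1)[:k]
                    chosen = remaining[part]
                lc[t].ravel()[chosen] = c
                mask = np.ones(remaining.size, dtype=bool)
                if k < remaining.size:
                    mask[part] = False
                    remaining = remaining[mask]
                else:
                    remaining = remaining[:0]
            lc[t].ravel()[remaining] = order_codes[-1]
    return lc


def _population(spec: RegionSpec, land_cover: np.ndarray) -> np.ndarray:
    """Settlement-weighted population rasters, shape (T, H, W).

    Regional totals grow geometrically to ``1 + population_growth`` over the
    whole period; within the region, density follows a smoothed settlement
    kernel plus a small rural baseline, so municipalities that urbanize
    attract a growing population share.
    """
    n_t = spec.n_timesteps
    pop = np.empty_like(land_cover, dtype=float)
    growth = 1.0 + spec.population_growth
    for t in range(n_t):
        total = spec.population_total * growth ** (t / (n_t - 1))
        dens = gaussian_filter((land_cover[t] == _SET).astype(float), 2.0) + 0.1
        pop[t] = dens / dens.sum() * total
    return pop


def _protection(
    spec: RegionSpec,
    zones: np.ndarray,
    land_cover_t0: np.ndarray,
    templates: list[ArchetypeTemplate],
    labels: np.ndarray,
) -> np.ndarray:
    """Static protection-level raster (levels 0..4).

    Each municipality protects its archetype's share of pixels, preferring
    natural land covers; protected pixels are banded into levels 1..4 by a
    smooth latent score (top band = strictest protection).
    """
    h, w = spec.grid_shape
    rng = substream(spec.seed, "protection")
    latent = gaussian_filter(rng.standard_normal((h, w)), 3.0)
    latent = (latent - latent.mean()) / (latent.std() + 1e-12)
    natural = np.isin(
        land_cover_t0, [LC_CODE[c] for c in _NATURAL_CLASSES]
    ).astype(float)
    score = (latent + 1.5 * natural).ravel()
    protection = np.zeros(h * w, dtype=np.int8)
    zone_flat = zones.ravel()
    for m in range(spec.n_municipalities):
        idx = np.flatnonzero(zone_flat == m)
        n_prot = int(round(templates[labels[m]].protected_fraction * idx.size))
        if n_prot == 0:
            continue
        top = idx[np.argsort(-score[idx], kind="stable")[:n_prot]]
        # split by rank into 4 bands: strictest protection = best score
        bands = np.array_split(top, 4)
        for level, band in zip((4, 3, 2, 1), bands):
            protection[band] = level
    return protection.reshape(h, w)


def _threat_layers(land_cover: np.ndarray) -> dict[str, np.ndarray]:
    """Land-cover-derived threat intensity rasters in [0, 1] per timestep."""
    urban = (land_cover == _SET).astype(float)
    agri = 0.8 * np.isin(
        land_cover, [LC_CODE["cropland"], LC_CODE["horticulture"]]
    ).astype(float)
    return {"urban": urban, "agriculture": agri}


def _climate(spec: RegionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Static precipitation and PET rasters (mm/yr).

    A gentle gradient plus smooth local variation in a humid temperate range
    (P ~ 1000-1300, PET ~ 550-650): at canton scale climate varies far less
    than land use, so water-yield differences are driven mostly by cover.
    """
    h, w = spec.grid_shape
    rng = substream(spec.seed, "climate")
    grad = np.linspace(0.0, 1.0, h)[:, None] * np.ones((1, w))

    def smooth() -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((h, w)), 8.0)
        return (f - f.mean()) / (f.std() + 1e-12)

    precip = np.clip(1050.0 + 150.0 * grad + 40.0 * smooth(), 400.0, None)
    pet = np.clip(620.0 - 50.0 * grad + 20.0 * smooth(), 200.0, None)
    return precip, pet


def default_econ_tables(n_timesteps: int = 4) -> EconTables:
    """Socio-economic rate tables for the synthetic region.

    Magnitudes follow central-European conditions: cereal-dominated cropland
    (~6 t/ha), intensive horticulture, cattle on pasture, ~700 kg food and
    ~110 m3 household water per person-year, per-capita CO2e declining from
    ~8.5 to ~6 t over the four decades.
    """
    return EconTables(
        crop_yield={"cropland": 6000.0, "horticulture": 25000.0},
        crop_pollinator_dependence={"cropland": 0.25, "horticulture": 0.65},
        livestock_density={"cattle": 1.2},
        meat_per_animal={"cattle": 250.0},
        per_capita_food_demand=700.0,
        per_capita_water_demand=110.0,
        sectoral_water_demand={
            "settlement": 25.0,
            "cropland": 15.0,
            "horticulture": 40.0,
        },
        per_capita_co2e=tuple(np.linspace(8.5, 6.0, n_timesteps)),
        npp_by_class={
            "settlement": 0.5,
            "cropland": 4.5,
            "horticulture": 3.0,
            "forest": 6.0,
            "meadow_pasture": 4.0,
            "water": 0.2,
            "park_public": 2.0,
            "other": 1.0,
        },
        recreation_value_by_class={
            "settlement": 0.1,
            "cropland": 0.3,
            "horticulture": 0.2,
            "forest": 0.8,
            "meadow_pasture": 0.6,
            "water": 0.7,
            "park_public": 1.0,
            "other": 0.4,
        },
        per_capita_recreation_need=30.0,
    )


def generate_region(spec: RegionSpec) -> tuple[LandscapeStack, EconTables]:
    """Generate a synthetic landscape stack and its economic tables.

    Deterministic for a fixed seed; municipalities are assigned to planted
    archetypes (see :func:`planted_labels`), each with a distinct land-cover
    trajectory, so downstream trend tables separate by archetype.
    """
    labels = planted_labels(spec)
    templates = make_templates(spec.n_archetypes, substream(spec.seed, "templates"))
    zones, seed_distance = _voronoi_zones(spec)
    fractions = _municipality_fractions(spec, templates, labels)
    suitability = _suitability_fields(spec, seed_distance)
    land_cover = _allocate_land_cover(spec, zones, fractions, suitability)
    population = _population(spec, land_cover)
    protection = _protection(spec, zones, land_cover[0], templates, labels)
    precip, pet = _climate(spec)
    stack = LandscapeStack(
        land_cover=land_cover,
        population=population,
        protection=protection,
        threat_layers=_threat_layers(land_cover),
        precipitation=precip,
        pet=pet,
        zones=zones,
        pixel_area=spec.pixel_area,
        timestep_labels=tuple(spec.timestep_labels),
    )
    return stack, default_econ_tables(spec.n_timesteps)
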