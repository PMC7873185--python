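"""Synthetic study generator: landscape series, species pools, and surveys.

Everything downstream (metrics, community-weighted moments, null models,
time-lagged regressions) is exercised against data produced here, with a
*known* ground truth: trait filtering is explicit and tunable, so tests can
ask whether the inference machinery recovers what the generator put in.

The emulated design is an agricultural valley study: twenty 1 km x 1 km
landscape windows spanning independent gradients of compositional and
configurational heterogeneity, mapped at three years over which grassland is
converted to crop and hedgerow length is lost; current plant assemblages
surveyed in grassland plots (16 quadrats each) and hedgerow sections, birds
at 4 point counts per window; five functional traits per taxon.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import line as _raster_line

from .landscape import (
    ARTIFICIAL,
    CROP,
    GRASSLAND,
    HEDGEROW,
    ORCHARD,
    WATER,
    WOODLAND,
    HedgerowNetwork,
    LandUseMap,
    PREDICTOR_NAMES,
)

TAXA: tuple[str, ...] = ("hedgerow_plants", "grassland_plants", "birds")

#: Habitat surveyed for each taxon ("all" = whole window, birds).
TAXON_HABITAT: dict[str, str] = {
    "hedgerow_plants": "hedgerow",
    "grassland_plants": "grassland",
    "birds": "all",
}


@dataclasses.dataclass(frozen=True)
class TraitDistributionSpec:
    """Range and moments of one trait in the regional species pool.

    ``discrete`` marks ordinal index traits (values rounded to integers of
    ``[minimum, maximum]``). Heavily right-skewed traits (sd > mean: seed
    mass, body mass) are drawn log-normally with moment matching; the rest
    normally; all draws are clipped to ``[minimum, maximum]``.
    """

    name: str
    minimum: float
    maximum: float
    mean: float
    sd: float
    discrete: bool = False

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError(
                f"trait {self.name!r}: need min <= mean <= max, "
                f"got {self.minimum}, {self.mean}, {self.maximum}"
            )
        if self.sd <= 0:
            raise ValueError(f"trait {self.name!r}: SD must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd > self.mean:  # right-skewed: log-normal, moment-matched
            sigma2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2
            values = rng.lognormal(mu, math.sqrt(sigma2), size=n)
        else:
            values = rng.normal(self.mean, self.sd, size=n)
        values = np.clip(values, self.minimum, self.maximum)
        if self.discrete:
            values = np.clip(np.rint(values), self.minimum, self.maximum)
        return values


#: Plant trait pool (dispersal / reproduction / life-cycle); ordinal indices
#: for clonal allocation (1-5) and lifespan (1-4), months for phenology,
#: milligrams for seed mass.
PLANT_TRAIT_SPECS: dict[str, TraitDistributionSpec] = {
    s.name: s
    for s in (
        TraitDistributionSpec("seed_mass", 0.01, 47.6, 2.6, 6.0),
        TraitDistributionSpec("clonal_index", 1, 5, 2.3, 1.0, discrete=True),
        TraitDistributionSpec("flowering_onset", 1, 9, 5.7, 1.2),
        TraitDistributionSpec("flowering_duration", 1, 12, 3.6, 1.7),
        TraitDistributionSpec("lifespan_index", 1, 4, 3.3, 1.2, discrete=True),
    )
}

#: Bird trait pool; grams, counts, months, years.
BIRD_TRAIT_SPECS: dict[str, TraitDistributionSpec] = {
    s.name: s
    for s in (
        TraitDistributionSpec("body_mass", 8.5, 10950.0, 331.8, 1256.0),
        TraitDistributionSpec("egg_number", 2, 12, 5.6, 2.1),
        TraitDistributionSpec("breeding_onset", 4, 7, 5.3, 1.0),
        TraitDistributionSpec("brood_number", 1, 3.5, 1.7, 1.0),
        TraitDistributionSpec("lifespan", 5, 39, 14.8, 6.8),
    )
}

TRAIT_SPECS_BY_TAXON: dict[str, dict[str, TraitDistributionSpec]] = {
    "hedgerow_plants": PLANT_TRAIT_SPECS,
    "grassland_plants": PLANT_TRAIT_SPECS,
    "birds": BIRD_TRAIT_SPECS,
}


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """One ground-truth trait filter applied during community assembly.

    A Gaussian kernel in normalised trait space multiplies each species'
    per-quadrat occurrence probability:

    * ``mode="convergent"`` — ``exp(-strength * (z_i - opt_k)^2)`` with the
      optimum ``opt_k`` an affine map of landscape variable ``variable`` at
      ``lag_year`` into the trait range (windows with high values of the
      variable favour high trait values);
    * ``mode="divergent"`` — a two-optimum kernel at the trait extremes,
      pushing occurrence weight toward both tails.

    ``target`` chooses the assembly stage the kernel acts on:
    ``"dominance"`` (default) filters occurrence rates given presence — the
    structure the occurrence-rate null model (NM2) tests, with presence
    sustained by propagule influx (mass effect); ``"incidence"`` filters
    which species are present at all — what the species-selection null
    model (NM1) tests; ``"both"`` filters the two stages together.

    ``strength = 0`` is neutral assembly.
    """

    taxon: str
    trait: str
    variable: str
    lag_year: str
    strength: float
    mode: str = "convergent"
    target: str = "dominance"

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("filter strength must be >= 0")
        if self.mode not in ("convergent", "divergent"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.target not in ("dominance", "incidence", "both"):
            raise ValueError(f"unknown filter target {self.target!r}")
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}")
        if self.trait not in TRAIT_SPECS_BY_TAXON[self.taxon]:
            raise ValueError(f"unknown trait {self.trait!r} for {self.taxon}")
        if self.variable not in PREDICTOR_NAMES:
            raise ValueError(f"unknown landscape variable {self.variable!r}")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study; defaults emulate the field design."""

    n_windows: int = 20
    window_size_m: float = 1000.0
    cell_size_m: float = 10.0
    years: tuple[str, ...] = ("40_years_ago", "15_years_ago", "current")
    n_hedgerow_plants: int = 241
    n_grassland_plants: int = 173
    n_birds: int = 84
    #: per-interval mean fraction of grassland cells converted to crop
    #: (large first interval: the major conversion wave, then a slower one)
    grassland_to_crop: tuple[float, ...] = (0.40, 0.15)
    #: per-interval mean fraction of hedgerow length removed
    hedgerow_loss: tuple[float, ...] = (0.35, 0.15)
    #: Beta concentration of per-window conversion intensities around the
    #: interval mean; windows intensify unevenly (0 disables heterogeneity)
    conversion_concentration: float = 3.0
    #: windows with no grassland at any year / no hedgerows at any year
    n_windows_without_grassland: int = 5
    n_windows_without_hedgerow: int = 2
    #: ground-truth filters (empty = neutral assembly)
    filters: tuple[FilterSpec, ...] = ()
    #: Voronoi seed-count range controlling configurational heterogeneity
    patch_seed_range: tuple[int, int] = (8, 80)
    #: grassland share range across grassland-bearing windows
    grassland_share_range: tuple[float, float] = (0.15, 0.60)
    #: lattice keep-probability range controlling hedgerow density
    hedgerow_density_range: tuple[float, float] = (0.12, 0.50)
    hedgerow_spacing_m: float = 100.0
    #: survey design: plots/sections per window, quadrats per unit, bird points
    grassland_plots_range: tuple[int, int] = (12, 27)
    grassland_quadrats_per_plot: int = 16
    hedgerow_sections_range: tuple[int, int] = (8, 20)
    hedgerow_quadrats_per_section: int = 10
    bird_points: int = 4
    #: mean per-window richness the occupancy model is calibrated to
    #: (midpoints of the emulated study's observed ranges)
    richness_targets: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "hedgerow_plants": 83.0,
            "grassland_plants": 55.0,
            "birds": 21.0,
        }
    )
    #: log-SD of the window-level occupancy multiplier (sampling/context
    #: noise, independent of the landscape by design)
    window_effect_sd: float = 0.25
    abundance_sigma: float = 1.5
    #: local dominance given presence: mean per-quadrat (plants) or
    #: per-point (birds) occupancy, and the log-SD of its window x species
    #: variation (local conditions, not regional abundance, set who
    #: dominates within a window); birds sit higher because a present
    #: territorial species is detected at most of the four point counts
    local_occupancy: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "hedgerow_plants": 0.1,
            "grassland_plants": 0.1,
            "birds": 0.45,
        }
    )
    local_dominance_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_windows < 2:
            raise ValueError("n_windows must be >= 2")
        if len(self.years) < 1 or len(set(self.years)) != len(self.years):
            raise ValueError("years must be distinct labels in temporal order")
        n_intervals = len(self.years) - 1
        for name, fracs in (
            ("grassland_to_crop", self.grassland_to_crop),
            ("hedgerow_loss", self.hedgerow_loss),
        ):
            if len(fracs) < n_intervals:
                raise ValueError(f"{name} must cover {n_intervals} intervals")
            if any(not 0 <= f <= 1 for f in fracs):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
        n_cells, rem = divmod(self.window_size_m, self.cell_size_m)
        if rem != 0 or n_cells < 2:
            raise ValueError("cell_size_m must divide window_size_m")
        if (
            self.n_windows_without_grassland + self.n_windows_without_hedgerow
            > self.n_windows
        ):
            raise ValueError("more habitat-free windows than windows")
        for f in self.filters:
            if f.lag_year not in self.years:
                raise ValueError(f"filter lag year {f.lag_year!r} not in years")

    @property
    def n_cells(self) -> int:
        return int(self.window_size_m // self.cell_size_m)

    def window_ids(self) -> list[str]:
        return [f"w{i + 1:02d}" for i in range(self.n_windows)]


# ---------------------------------------------------------------------------
# species pools


def generate_species_pool(
    trait_specs: Mapping[str, TraitDistributionSpec],
    n_species: int,
    seed: int | np.random.Generator,
    prefix: str = "sp",
    abundance_sigma: float = 1.5,
) -> pd.DataFrame:
    """Regional species pool: ids, genera, trait values, regional abundances.

    Trait values are drawn independently per trait from their pool
    distributions (clipped, ordinal traits rounded). Regional relative
    abundances follow a log-normal rank-abundance curve, normalised to sum
    to 1; they drive both survey occupancy and the species-selection null
    model's draw probabilities.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    species = [f"{prefix}_{i + 1:03d}" for i in range(n_species)]
    n_genera = max(1, n_species // 3)
    genera = rng.integers(0, n_genera, size=n_species)
    pool = pd.DataFrame(
        {
            "species": species,
            "genus": [f"{prefix}_gen{g + 1:03d}" for g in genera],
        }
    )
    for name, spec in trait_specs.items():
        pool[name] = spec.sample(n_species, rng)
    abundance = rng.lognormal(0.0, abundance_sigma, size=n_species)
    pool["regional_abundance"] = abundance / abundance.sum()
    return pool.set_index("species")


# ---------------------------------------------------------------------------
# landscape series


@dataclasses.dataclass
class LandscapeSeries:
    """Maps and hedgerow networks for every (window, year)."""

    maps: dict[tuple[str, str], LandUseMap]
    networks: dict[tuple[str, str], HedgerowNetwork]
    windows: list[str]
    years: tuple[str, ...]


def _lattice_edges(window: float, spacing: float) -> np.ndarray:
    """All horizontal+vertical lattice edges of the hedgerow skeleton."""
    n = int(round(window / spacing))
    coords = np.arange(n + 1) * spacing
    edges = []
    for y in coords:
        for i in range(n):
            edges.append([[coords[i], y], [coords[i + 1], y]])
    for x in coords:
        for i in range(n):
            edges.append([[x, coords[i]], [x, coords[i + 1]]])
    return np.asarray(edges, dtype=float)


def _rasterize_segments(
    base: np.ndarray, segments: np.ndarray, cell: float
) -> np.ndarray:
    """Overlay hedgerow cells on a copy of the base class grid."""
    grid = base.copy()
    n = grid.shape[0]
    for (x0, y0), (x1, y1) in segments:
        r0, c0 = min(int(y0 // cell), n - 1), min(int(x0 // cell), n - 1)
        r1, c1 = min(int(y1 // cell), n - 1), min(int(x1 // cell), n - 1)
        rr, cc = _raster_line(r0, c0, r1, c1)
        grid[rr, cc] = HEDGEROW
    return grid


def _interval_fraction(mean: float, conc: float, rng: np.random.Generator) -> float:
    """Window-specific conversion intensity around the interval mean."""
    if mean in (0.0, 1.0) or conc <= 0:
        return mean
    return float(rng.beta(mean * conc, (1 - mean) * conc))


def generate_landscape_series(config: SyntheticConfig) -> LandscapeSeries:
    """Patch-seeded class mosaics plus lattice hedgerows, evolved over years.

    Each window's earliest-year map is a Voronoi mosaic: seed points are
    scattered (window-specific density controls configurational
    heterogeneity), cells take the class of their nearest seed, and class
    assignment probabilities (window-specific grassland share, crop share,
    Dirichlet remainder) control compositional heterogeneity. Later years are
    *derived* from earlier ones — never regenerated — by converting whole
    grassland patches (plus a partial patch to hit the cell budget) to crop
    and deleting hedgerow segments until the length budget is met, so lagged
    signals are well defined.
    """
    rng = np.random.default_rng([config.seed, 0])
    windows = config.window_ids()
    k = config.n_windows
    # structural gradients, shuffled across windows
    order = rng.permutation(k)
    no_hedge = set(order[: config.n_windows_without_hedgerow])
    no_grass = set(
        order[
            config.n_windows_without_hedgerow : config.n_windows_without_hedgerow
            + config.n_windows_without_grassland
        ]
    )
    lo, hi = config.patch_seed_range
    seed_counts = np.rint(np.geomspace(lo, hi, k)).astype(int)[rng.permutation(k)]
    n_grassy = k - len(no_grass)
    g_shares = np.zeros(k)
    g_shares[[i for i in range(k) if i not in no_grass]] = rng.permutation(
        np.linspace(*config.grassland_share_range, n_grassy)
    )
    n_hedgy = k - len(no_hedge)
    h_dens = np.zeros(k)
    h_dens[[i for i in range(k) if i not in no_hedge]] = rng.permutation(
        np.linspace(*config.hedgerow_density_range, n_hedgy)
    )

    n = config.n_cells
    cell = config.cell_size_m
    centers = np.stack(
        np.meshgrid(
            (np.arange(n) + 0.5) * cell, (np.arange(n) + 0.5) * cell, indexing="xy"
        ),
        axis=-1,
    ).reshape(-1, 2)  # (x, y) per cell in row-major (row=y, col=x) order
    all_edges = _lattice_edges(config.window_size_m, config.hedgerow_spacing_m)

    maps: dict[tuple[str, str], LandUseMap] = {}
    networks: dict[tuple[str, str], HedgerowNetwork] = {}
    for w_idx, window in enumerate(windows):
        wrng = np.random.default_rng([config.seed, 1, w_idx])
        seeds = wrng.uniform(0, config.window_size_m, size=(seed_counts[w_idx], 2))
        _, patch_of_cell = cKDTree(seeds).query(centers)
        patch_of_cell = patch_of_cell.reshape(n, n)
        g = g_shares[w_idx]
        crop_share = 0.5 * (1 - g)
        rest = wrng.dirichlet(np.ones(4)) * (1 - g - crop_share)
        probs = np.zeros(7)
        probs[GRASSLAND] = g
        probs[CROP] = crop_share
        probs[[ORCHARD, ARTIFICIAL, WOODLAND, WATER]] = rest
        patch_class = wrng.choice(7, size=len(seeds), p=probs / probs.sum())
        if g > 0 and GRASSLAND not in patch_class:
            # grassland-bearing windows must start with >= 1 grassland patch
            patch_class[wrng.integers(len(seeds))] = GRASSLAND
        base = patch_class[patch_of_cell].astype(np.int8)

        keep = wrng.random(len(all_edges)) < h_dens[w_idx]
        if h_dens[w_idx] > 0 and not keep.any():
            keep[wrng.integers(len(all_edges))] = True
        segments = all_edges[keep]

        for y_idx, year in enumerate(config.years):
            if y_idx > 0:
                # grassland -> crop, whole patches first, partial to hit budget
                frac = _interval_fraction(
                    config.grassland_to_crop[y_idx - 1],
                    config.conversion_concentration,
                    wrng,
                )
                grass_cells = int((base == GRASSLAND).sum())
                budget = math.ceil(frac * grass_cells)
                if config.grassland_to_crop[y_idx - 1] < 1.0:
                    # designated grassland windows keep a habitat remnant
                    # (>= 2% of the window) unless full conversion is asked
                    keep_floor = max(1, int(0.02 * base.size))
                    budget = max(0, min(budget, grass_cells - keep_floor))
                if budget > 0:
                    patches = np.unique(patch_of_cell[base == GRASSLAND])
                    for patch in wrng.permutation(patches):
                        mask = (patch_of_cell == patch) & (base == GRASSLAND)
                        size = int(mask.sum())
                        if size <= budget:
                            base[mask] = CROP
                            budget -= size
                        else:  # split the patch: convert column-ordered cells
                            rows, cols = np.nonzero(mask)
                            order_cells = np.lexsort((rows, cols))[:budget]
                            base[rows[order_cells], cols[order_cells]] = CROP
                            budget = 0
                        if budget == 0:
                            break
                # hedgerow loss: drop whole segments until the length budget
                loss = _interval_fraction(
                    config.hedgerow_loss[y_idx - 1],
                    config.conversion_concentration,
                    wrng,
                )
                if len(segments) and loss > 0:
                    lengths = np.hypot(
                        *(segments[:, 1] - segments[:, 0]).T
                    )
                    target = loss * lengths.sum()
                    # hedgerow-bearing windows keep a remnant network unless
                    # total loss is explicitly configured
                    max_drop = (
                        len(segments)
                        if config.hedgerow_loss[y_idx - 1] >= 1.0
                        else max(0, len(segments) - 2)
                    )
                    drop_order = wrng.permutation(len(segments))
                    removed, dropped = 0.0, []
                    for s_i in drop_order:
                        if removed >= target or len(dropped) >= max_drop:
                            break
                        dropped.append(s_i)
                        removed += lengths[s_i]
                    keep_mask = np.ones(len(segments), bool)
                    keep_mask[dropped] = False
                    segments = segments[keep_mask]
            grid = _rasterize_segments(base, segments, cell)
            maps[(window, year)] = LandUseMap(grid, cell, window, year)
            networks[(window, year)] = HedgerowNetwork(
                segments.copy(), window, year
            )
    return LandscapeSeries(maps, networks, windows, tuple(config.years))


# ---------------------------------------------------------------------------
# community assembly


def _normalised_variable(
    landscape_vars: pd.DataFrame, variable: str, year: str
) -> pd.Series:
    """Landscape variable at one year, min-max normalised across windows.

    Windows where the variable is undefined (absent habitat) sit at 0.5,
    i.e. a mid-range trait optimum.
    """
    sub = landscape_vars[landscape_vars["year"] == year].set_index("window")
    if variable not in sub.columns:
        raise ValueError(f"unknown landscape variable {variable!r}")
    v = sub[variable].astype(float)
    lo, hi = v.min(skipna=True), v.max(skipna=True)
    if not np.isfinite(lo) or hi == lo:
        z = pd.Series(0.5, index=v.index)
    else:
        z = (v - lo) / (hi - lo)
    return z.fillna(0.5)


def _filter_kernel(
    z_trait: np.ndarray, opt: float, strength: float, mode: str
) -> np.ndarray:
    if mode == "convergent":
        f = np.exp(-strength * (z_trait - opt) ** 2)
    else:  # divergent: two optima near the trait extremes
        f = np.exp(-strength * (z_trait - 0.1) ** 2) + np.exp(
            -strength * (z_trait - 0.9) ** 2
        )
    m = f.max()
    return f / m if m > 0 else np.ones_like(f)


def _calibrate_base_rate(
    abundance: np.ndarray, n_quadrats: int, target_richness: float
) -> float:
    """Solve the occupancy scale so expected richness hits the target.

    Per-quadrat occurrence probability is ``min(b * a_i, 0.95)``; a species
    is recorded when it occurs in >= 1 of ``n_quadrats`` quadrats. Expected
    richness is monotone in ``b``, so bisection suffices.
    """
    target = min(target_richness, 0.95 * len(abundance))

    def expected_richness(b: float) -> float:
        p = np.minimum(b * abundance, 0.95)
        return float((1.0 - (1.0 - p) ** n_quadrats).sum())

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if expected_richness(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def assemble_communities(
    pools: Mapping[str, pd.DataFrame],
    landscape_vars: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Survey tables per taxon, pooled per window, with known filtering.

    Two-stage occupancy model, reflecting the classic decoupling of regional
    incidence from local dominance:

    * **incidence** — species i is recorded in window k when it occurs in at
      least one of the window's quadrats (or bird points), each with
      probability ``min(b * a_i * u_k * f_ik, 0.95)``: regional relative
      abundance ``a_i`` makes common species present in more windows
      (``u_k`` is a landscape-independent window effect, ``f_ik`` the
      product of the configured trait-filter kernels, 1 under neutral
      assembly); the scale ``b`` is calibrated so mean richness matches the
      emulated study;
    * **dominance** — given presence, the occurrence count is
      ``1 + Binomial(M_k - 1, q_ik)`` with ``q_ik`` a window x species local
      occupancy (log-normal around ``local_occupancy``, times the filter
      kernel): who dominates a window is set by local conditions, not by
      regional abundance, so under neutral assembly the weight-trait pairing
      is independent across windows (the exchangeability the occurrence-rate
      null model tests against).

    Windows lacking a habitat emit no surveys for it.

    Returns a dict taxon -> DataFrame(window, habitat, species, count,
    max_count), one row per species actually recorded.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    current = config.years[-1]
    cur = landscape_vars[landscape_vars["year"] == current].set_index("window")
    windows = sorted(cur.index)

    surveys: dict[str, pd.DataFrame] = {}
    for taxon in TAXA:
        pool = pools[taxon]
        habitat = TAXON_HABITAT[taxon]
        if habitat == "hedgerow":
            present = [w for w in windows if cur.loc[w, "hedgerow_amount"] > 0]
            unit_lo, unit_hi = config.hedgerow_sections_range
            per_unit = config.hedgerow_quadrats_per_section
        elif habitat == "grassland":
            present = [w for w in windows if cur.loc[w, "grassland_amount"] > 0]
            unit_lo, unit_hi = config.grassland_plots_range
            per_unit = config.grassland_quadrats_per_plot
        else:
            present = list(windows)
            unit_lo = unit_hi = config.bird_points
            per_unit = 1

        abundance = pool["regional_abundance"].to_numpy()
        design_mid = per_unit * (unit_lo + unit_hi) // 2
        base = _calibrate_base_rate(
            abundance, design_mid, config.richness_targets[taxon]
        )

        # per-window filter kernels (one per assembly stage), neutral = 1
        inc_kernels = {w: np.ones(len(pool)) for w in present}
        dom_kernels = {w: np.ones(len(pool)) for w in present}
        for f in config.filters:
            if f.taxon != taxon or f.strength == 0:
                continue
            spec = TRAIT_SPECS_BY_TAXON[taxon][f.trait]
            z = (pool[f.trait].to_numpy() - spec.minimum) / (
                spec.maximum - spec.minimum
            )
            opt = _normalised_variable(landscape_vars, f.variable, f.lag_year)
            for w in present:
                k = _filter_kernel(z, float(opt.loc[w]), f.strength, f.mode)
                if f.target in ("incidence", "both"):
                    inc_kernels[w] = inc_kernels[w] * k
                if f.target in ("dominance", "both"):
                    dom_kernels[w] = dom_kernels[w] * k

        rows = []
        for w in present:
            units = int(rng.integers(unit_lo, unit_hi + 1))
            max_count = units * per_unit
            u_k = rng.lognormal(0.0, config.window_effect_sd)
            # incidence: a species is recorded at all when it occurs in at
            # least one quadrat at its abundance-driven occupancy
            p = np.minimum(base * abundance * u_k * inc_kernels[w], 0.95)
            occupied = rng.random(p.size) < 1.0 - (1.0 - p) ** max_count
            # dominance given presence: local, window-specific conditions
            eps = rng.lognormal(0.0, config.local_dominance_sigma, size=p.size)
            q = np.minimum(
                config.local_occupancy[taxon] * eps * dom_kernels[w], 0.9
            )
            counts = np.where(
                occupied, 1 + rng.binomial(max_count - 1, q), 0
            )
            found = np.nonzero(counts)[0]
            for i in found:
                rows.append(
                    {
                        "window": w,
                        "habitat": habitat,
                        "species": pool.index[i],
                        "count": int(counts[i]),
                        "max_count": max_count,
                    }
                )
        surveys[taxon] = pd.DataFrame(
            rows, columns=["window", "habitat", "species", "count", "max_count"]
        )
    return surveys


# ---------------------------------------------------------------------------
# one-call study generation


@dataclasses.dataclass
class StudyData:
    """A complete synthetic study: inputs for every downstream stage."""

    config: SyntheticConfig
    series: LandscapeSeries
    landscape_vars: pd.DataFrame
    pools: dict[str, pd.DataFrame]
    surveys: dict[str, pd.DataFrame]


def generate_study(
    config: SyntheticConfig, snap_tol: float = 0.5
) -> StudyData:
    """Generate landscapes, compute predictors, and assemble communities."""
    from .landscape import compute_landscape_variables

    series = generate_landscape_series(config)
    landscape_vars = compute_landscape_variables(
        series.maps, series.networks, snap_tol=snap_tol
    )
    pools = {
        taxon: generate_species_pool(
            TRAIT_SPECS_BY_TAXON[taxon],
            n,
            np.random.default_rng([config.seed, 3, t_idx]),
            prefix=("hp", "gp", "bd")[t_idx],
            abundance_sigma=config.abundance_sigma,
        )
        for t_idx, (taxon, n) in enumerate(
            zip(
                TAXA,
                (config.n_hedgerow_plants, config.n_grassland_plants, config.n_birds),
            )
        )
    }
    surveys = assemble_communities(pools, landscape_vars, config)
    return StudyData(config, series, landscape_vars, pools, surveys)
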