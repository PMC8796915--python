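"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators cover the pipeline's inputs end to end with no downloads:

* patchy landscapes — high-capacity agricultural corridors, zero-capacity
  water/barren cells and >600 m ridge barriers, emitted as land-cover and
  altitude rasters keyed to the shipped reclassification table;
* aligned sequence panels — evolved under HKY(+gamma) or K2P along a
  star-of-stars topology (group ancestors, then tips) with branch lengths
  chosen so expected pairwise divergences hit the recipe targets, e.g.
  ~0.5-1.9% within-mitotype mtCOI spread or two nuclear allele clades
  ~1.5% apart.

Every generator is a pure function of its recipe and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import ReclassTable, build_landscape, default_reclass_table
from .raster_io import GridSpec, RasterLayer
from .seqdist import (
    SubstitutionModel,
    TrimmedAlignment,
    discrete_gamma_rates,
    hky_transition_matrix,
)
from .simulator import DispersalParams, SimulationConfig, derive_rates

__all__ = [
    "LandscapeRecipe",
    "PanelRecipe",
    "RecipeError",
    "make_landscape",
    "simulate_sequences",
    "evolve_sequence",
    "make_two_origin_fixture",
]

# class codes from the shipped reclass table used by the generators
_AGRICULTURE = 18
_SAVANNA = 14
_WATER = 21
_DENSE_FOREST = 1
_INTERMEDIATE_CODES = {0.1: _DENSE_FOREST, 0.2: 17, 0.3: 8, 0.5: _SAVANNA, 1.0: _AGRICULTURE}
_LOWLAND_M = 200.0
_RIDGE_M = 700.0


class RecipeError(ValueError):
    """Contradictory or infeasible generator recipe."""


@dataclass(frozen=True)
class LandscapeRecipe:
    """A rectangular habitat mosaic with corridors and barriers.

    ``corridor_rows``/``corridor_cols`` become intensive agriculture
    (k_rel = 1); ``barrier_rows``/``barrier_cols`` become impassable, as a
    >600 m ridge or as water depending on ``barrier_kind``.  Remaining
    cells take the class whose k_rel is closest to ``background_k_rel``,
    with a seeded fraction of mosaic noise from other intermediate classes.
    """

    nrows: int
    ncols: int
    corridor_rows: tuple = ()
    corridor_cols: tuple = ()
    barrier_rows: tuple = ()
    barrier_cols: tuple = ()
    barrier_kind: str = "ridge"  # or "water"
    background_k_rel: float = 0.5
    noise_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise RecipeError("landscape must be at least 1x1")
        if self.barrier_kind not in ("ridge", "water"):
            raise RecipeError(f"unknown barrier kind {self.barrier_kind!r}")
        if not (0.0 <= self.background_k_rel <= 1.0):
            raise RecipeError("background_k_rel must lie in [0,1]")
        for r in (*self.corridor_rows, *self.barrier_rows):
            if not 0 <= r < self.nrows:
                raise RecipeError(f"row {r} out of bounds")
        for c in (*self.corridor_cols, *self.barrier_cols):
            if not 0 <= c < self.ncols:
                raise RecipeError(f"col {c} out of bounds")
        overlap_r = set(self.corridor_rows) & set(self.barrier_rows)
        overlap_c = set(self.corridor_cols) & set(self.barrier_cols)
        if overlap_r or overlap_c:
            raise RecipeError(
                f"corridor and barrier overlap: rows {sorted(overlap_r)}, cols {sorted(overlap_c)}"
            )


def make_landscape(recipe: LandscapeRecipe) -> tuple[RasterLayer, RasterLayer, ReclassTable]:
    """Build (cover, altitude, table) rasters realising the recipe."""
    rng = np.random.default_rng(recipe.seed)
    spec = GridSpec(ncols=recipe.ncols, nrows=recipe.nrows, cellsize=1.0)

    bg_code = min(_INTERMEDIATE_CODES.items(), key=lambda kv: abs(kv[0] - recipe.background_k_rel))[1]
    cover = np.full((recipe.nrows, recipe.ncols), bg_code, dtype=float)
    if recipe.noise_fraction > 0:
        noisy = rng.random(cover.shape) < recipe.noise_fraction
        alt_codes = [c for c in _INTERMEDIATE_CODES.values() if c != bg_code]
        cover[noisy] = rng.choice(alt_codes, size=int(noisy.sum()))

    for r in recipe.corridor_rows:
        cover[r, :] = _AGRICULTURE
    for c in recipe.corridor_cols:
        cover[:, c] = _AGRICULTURE

    alt = np.full(cover.shape, _LOWLAND_M)
    for r in recipe.barrier_rows:
        if recipe.barrier_kind == "ridge":
            alt[r, :] = _RIDGE_M
        else:
            cover[r, :] = _WATER
    for c in recipe.barrier_cols:
        if recipe.barrier_kind == "ridge":
            alt[:, c] = _RIDGE_M
        else:
            cover[:, c] = _WATER

    return RasterLayer(spec, cover), RasterLayer(spec, alt), default_reclass_table()


@dataclass(frozen=True)
class PanelRecipe:
    """A star-of-stars sequence panel.

    ``n_groups`` clades of ``n_haplotypes`` tips each; expected pairwise
    divergence is ``within_group_divergence`` inside a clade and
    ``between_group_divergence`` across clades (substitutions/site).  An
    optional outgroup sits at ``outgroup_divergence`` from every tip.
    """

    n_haplotypes: int
    length: int
    within_group_divergence: float
    between_group_divergence: float
    n_groups: int = 2
    outgroup_divergence: float = 0.0
    include_group_ancestors: bool = False
    model: SubstitutionModel = field(default_factory=lambda: SubstitutionModel("HKY+G", kappa=4.0, alpha=0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1 or self.length < 1 or self.n_groups < 1:
            raise RecipeError("need at least one group, one tip and one site")
        w, b = self.within_group_divergence, self.between_group_divergence
        if w < 0 or b < 0:
            raise RecipeError("divergences must be non-negative")
        if b < w:
            raise RecipeError("between-group divergence must be >= within-group")
        if max(b, self.outgroup_divergence) >= 1.0:
            raise RecipeError("target divergence too close to saturation")
        if self.outgroup_divergence and self.outgroup_divergence < b:
            raise RecipeError("outgroup divergence must be >= between-group divergence")


def _model_machinery(model: SubstitutionModel):
    freqs = np.asarray(model.base_freqs, dtype=float) if model.base_freqs is not None else np.full(4, 0.25)
    kappa = model.kappa if model.kappa is not None else (2.0 if model.name == "K2P" else 4.0)
    if model.name == "K2P":
        freqs = np.full(4, 0.25)
        rates = np.ones(1)
    else:
        rates = discrete_gamma_rates(model.alpha, model.ncat)
    return freqs, kappa, rates


def evolve_sequence(
    parent: np.ndarray,
    t: float,
    freqs: np.ndarray,
    kappa: float,
    site_rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one branch of length t; ``site_rates`` is the per-site rate
    multiplier, shared across all branches of a tree so among-site rate
    variation behaves as the estimators assume."""
    child = parent.copy()
    for r in np.unique(site_rates):
        P = hky_transition_matrix(t * r, freqs, kappa)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        sel_rate = site_rates == r
        for base in range(4):
            sel = sel_rate & (parent == base)
            n = int(sel.sum())
            if n:
                child[sel] = rng.choice(4, size=n, p=P[base])
    return child


def simulate_sequences(recipe: PanelRecipe) -> TrimmedAlignment:
    """Evolve the panel: root -> group ancestors -> tips (star-of-stars).

    Tip branches are within/2 and group branches (between - within)/2, so
    expected pairwise divergence matches the recipe targets.
    """
    freqs, kappa, rates = _model_machinery(recipe.model)
    rng = np.random.default_rng(recipe.seed)
    L = recipe.length
    b_tip = recipe.within_group_divergence / 2.0
    b_group = (recipe.between_group_divergence - recipe.within_group_divergence) / 2.0

    site_rates = rates[rng.integers(len(rates), size=L)]
    root = rng.choice(4, size=L, p=freqs).astype(np.uint8)

    records = []
    for g in range(recipe.n_groups):
        ancestor = evolve_sequence(root, b_group, freqs, kappa, site_rates, rng)
        if recipe.include_group_ancestors:
            # the clade's archetype sequence, usable as a reference panel entry
            records.append((f"g{g + 1}_ref", ancestor))
        for i in range(recipe.n_haplotypes):
            tip = evolve_sequence(ancestor, b_tip, freqs, kappa, site_rates, rng)
            records.append((f"g{g + 1}_t{i + 1}", tip))
    if recipe.outgroup_divergence > 0:
        b_out = recipe.outgroup_divergence - b_group - b_tip
        out = evolve_sequence(root, b_out, freqs, kappa, site_rates, rng)
        records.append(("outgroup", out))
    return TrimmedAlignment.from_sequences(records)


# --- two-origin simulation fixture -------------------------------------------

_FIXTURE_SEED = 20220123
_FIXTURE_SHAPE = (100, 100)
_FIXTURE_ORIGINS = ((30, 84), (70, 84))
_FIXTURE_RADIUS = 15
_COAST_COL = 85


def make_two_origin_fixture(founders: float = 100.0) -> SimulationConfig:
    """A two-introduction miniature: two coastal origins, 30 generations.

    The ~100x100 grid is water except for two habitable coastal blobs
    (radius 15 demes) around the origins, textured with savanna plus an
    agricultural corridor row through each origin.  Habitable demes sit
    within the 30-generation reach of the front, so the merged two-origin
    run colonises every habitable deme.  Deterministic: fixed internal
    seed; identical across calls.
    """
    nrows, ncols = _FIXTURE_SHAPE
    rng = np.random.default_rng(_FIXTURE_SEED)
    spec = GridSpec(ncols=ncols, nrows=nrows, cellsize=1.0)

    rr, cc = np.mgrid[0:nrows, 0:ncols]
    habitable = np.zeros((nrows, ncols), dtype=bool)
    for orow, ocol in _FIXTURE_ORIGINS:
        habitable |= np.hypot(rr - orow, cc - ocol) <= _FIXTURE_RADIUS
    habitable &= cc <= _COAST_COL  # Atlantic coastline on the east

    cover = np.full((nrows, ncols), float(_WATER))
    cover[habitable] = _SAVANNA
    noisy = habitable & (rng.random((nrows, ncols)) < 0.15)
    cover[noisy] = _AGRICULTURE
    for orow, _ in _FIXTURE_ORIGINS:
        band = habitable & (np.abs(rr - orow) <= 1)
        cover[band] = _AGRICULTURE

    alt = RasterLayer(spec, np.full((nrows, ncols), _LOWLAND_M))
    ls = build_landscape(RasterLayer(spec, cover), alt)
    return SimulationConfig(
        landscape=ls,
        rates=derive_rates(54.30),
        dispersal=DispersalParams(),
        origins=[(r, c, founders) for r, c in _FIXTURE_ORIGINS],
        n_generations=30,
        snapshot_every=5,
        growth_form="beverton-holt",
    )
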