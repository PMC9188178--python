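"""Synthetic seed spectra, hypercubes and feature tables.

The generator mimics the spectral structure the analysis assumes: each
variety has a smooth reflectance baseline rising toward the NIR (always
below 0.8) with Gaussian absorption features in the protein-linked
400–500 nm region, the starch/oil-linked 500–750 nm region and the
~980 nm water band.  Non-target varieties are generated from the target
by perturbing the absorption-band depths along a seeded random direction
scaled by a divergence knob ``d``; lots share a constant reflectance
shift and individual seeds add spectrally smooth noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .hsi import Hypercube
from .segmentation import SeedMask, SpectrumTable

__all__ = [
    "AbsorptionBand",
    "VarietySpec",
    "ScenarioConfig",
    "default_grid",
    "target_variety_spec",
    "make_variety_spec",
    "simulate_spectra",
    "simulate_hypercube",
    "simulate_feature_table",
    "simulate_scenario",
    "confusable_scenario",
    "generalization_scenario",
    "rich_target_spec",
]

REFLECTANCE_CAP = 0.8
NOISE_BANDWIDTH_NM = 20.0  # smoothing scale of the per-seed noise


def default_grid(step_nm: float = 4.0) -> np.ndarray:
    """Wavelength grid covering the retained 400–1000 nm interval."""
    return np.arange(400.0, 1000.0 + 0.5 * step_nm, step_nm)


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption feature: reflectance dip of ``depth`` at ``center_nm``."""

    center_nm: float
    depth: float
    width_nm: float


@dataclass(frozen=True)
class VarietySpec:
    """Spectral signature and variability of one simulated variety.

    The noiseless mean spectrum is a logistic ramp from ``base_lo`` to
    ``base_hi`` (centred at ``ramp_center_nm``) minus the sum of the
    Gaussian absorption bands.  ``lot_sigma`` scales constant between-lot
    shifts; ``seed_sigma`` scales smooth within-lot seed noise;
    ``divergence`` records how far this variety's band depths sit from
    the target's.
    """

    name: str
    base_lo: float = 0.15
    base_hi: float = 0.65
    ramp_center_nm: float = 720.0
    ramp_width_nm: float = 90.0
    bands: tuple[AbsorptionBand, ...] = (
        AbsorptionBand(455.0, 0.08, 28.0),   # protein-linked region
        AbsorptionBand(620.0, 0.10, 55.0),   # starch/oil-linked region
        AbsorptionBand(980.0, 0.12, 24.0),   # water band (O-H overtone)
    )
    lot_sigma: float = 0.008
    seed_sigma: float = 0.02
    noise_bandwidth_nm: float = NOISE_BANDWIDTH_NM
    divergence: float = 0.0

    def mean_spectrum(self, grid: np.ndarray) -> np.ndarray:
        """Analytic noiseless reflectance on ``grid`` (no clipping)."""
        grid = np.asarray(grid, dtype=float)
        ramp = self.base_lo + (self.base_hi - self.base_lo) / (
            1.0 + np.exp(-(grid - self.ramp_center_nm) / self.ramp_width_nm)
        )
        dips = np.zeros_like(grid)
        for band in self.bands:
            dips += band.depth * np.exp(-0.5 * ((grid - band.center_nm) / band.width_nm) ** 2)
        return ramp - dips


def target_variety_spec(name: str = "target", **overrides) -> VarietySpec:
    """The reference (target-variety) signature."""
    return replace(VarietySpec(name=name), **overrides)


def make_variety_spec(
    target: VarietySpec,
    d: float,
    seed: int = 0,
    band_mask=None,
    name: str | None = None,
) -> VarietySpec:
    """Derive a variety whose band depths sit at divergence ``d`` from ``target``.

    The perturbation is ``d`` times a seeded unit direction over the band
    depths (optionally restricted by ``band_mask``), so the distance
    between mean spectra is exactly linear in ``d``.
    """
    if d < 0:
        raise ValueError("divergence must be non-negative")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(len(target.bands))
    if band_mask is not None:
        u = u * np.asarray(band_mask, dtype=float)
    norm = np.linalg.norm(u)
    if norm > 0:
        u = u / norm
    bands = tuple(
        replace(b, depth=b.depth + d * ui) for b, ui in zip(target.bands, u)
    )
    return replace(
        target,
        name=name or f"{target.name}-d{d:g}",
        bands=bands,
        divergence=float(d),
    )


def _smooth_noise(
    rng: np.random.Generator,
    n_rows: int,
    grid: np.ndarray,
    sigma: float,
    bandwidth_nm: float = NOISE_BANDWIDTH_NM,
) -> np.ndarray:
    """Spectrally correlated noise with per-band std ~= sigma."""
    if sigma == 0:
        return np.zeros((n_rows, len(grid)))
    step = float(np.mean(np.diff(grid))) if len(grid) > 1 else 1.0
    smooth_px = bandwidth_nm / step
    white = rng.standard_normal((n_rows, len(grid)))
    smoothed = gaussian_filter1d(white, smooth_px, axis=1, mode="nearest")
    # per-band renormalization so every band (edges included) has std sigma
    operator = gaussian_filter1d(np.eye(len(grid)), smooth_px, axis=1, mode="nearest")
    row_scale = np.sqrt((operator**2).sum(axis=1))
    return sigma * smoothed / row_scale


def simulate_spectra(
    spec: VarietySpec,
    n_lots: int,
    seeds_per_lot: int,
    grid: np.ndarray | None = None,
    seed: int = 0,
    category: str = "target",
    surface: str = "unknown",
    lot_prefix: str | None = None,
) -> SpectrumTable:
    """Draw per-seed mean spectra for ``n_lots`` lots of one variety.

    spectrum = mean curve + constant lot shift (scale ``lot_sigma``)
    + smooth per-seed noise (scale ``seed_sigma``), clipped (with a
    warning) into the open interval (0, 0.8).
    """
    if n_lots < 1 or seeds_per_lot < 1:
        raise ValueError("need at least one lot and one seed per lot")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.min() < 400.0 - 1e-9 or grid.max() > 1000.0 + 1e-9:
        raise ValueError("grid must lie within [400, 1000] nm")
    rng = np.random.default_rng(seed)
    base = spec.mean_spectrum(grid)

    rows, lots = [], []
    prefix = lot_prefix or f"{spec.name}-lot"
    for lot in range(n_lots):
        shift = rng.normal(0.0, spec.lot_sigma) if spec.lot_sigma > 0 else 0.0
        noise = _smooth_noise(rng, seeds_per_lot, grid, spec.seed_sigma, spec.noise_bandwidth_nm)
        rows.append(base[np.newaxis, :] + shift + noise)
        lots.extend([f"{prefix}{lot + 1}"] * seeds_per_lot)
    spectra = np.vstack(rows)

    lo, hi = 1e-3, REFLECTANCE_CAP - 1e-3
    n_clip = int(((spectra < lo) | (spectra > hi)).sum())
    if n_clip:
        warnings.warn(
            f"{n_clip} simulated values clipped into (0, {REFLECTANCE_CAP})", stacklevel=2
        )
        spectra = np.clip(spectra, lo, hi)

    meta = pd.DataFrame(
        {
            "category": [category] * len(spectra),
            "variety": [spec.name] * len(spectra),
            "lot": lots,
            "surface": [surface] * len(spectra),
        }
    )
    return SpectrumTable(spectra, grid, meta)


# ---------------------------------------------------------------------------
# hypercube rendering
# ---------------------------------------------------------------------------

def _auto_layout(n_seeds: int, shape: tuple[int, int], rng: np.random.Generator):
    """Place up to n_seeds ellipses on a non-touching grid; error if they cannot fit."""
    rows, cols = shape
    per_row = int(np.ceil(np.sqrt(n_seeds)))
    n_rows = int(np.ceil(n_seeds / per_row))
    cell_h, cell_w = rows // n_rows, cols // per_row
    r_max = max(min(cell_h, cell_w) // 2 - 2, 1)
    if r_max < 2:
        raise ValueError(f"image {shape} too small for {n_seeds} non-touching seeds")
    layout = []
    for k in range(n_seeds):
        i, j = divmod(k, per_row)
        cy = i * cell_h + cell_h // 2
        cx = j * cell_w + cell_w // 2
        ry = int(rng.integers(max(2, r_max - 2), r_max + 1))
        rx = int(rng.integers(max(2, r_max - 2), r_max + 1))
        layout.append((cy, cx, ry, rx))
    return layout


def simulate_hypercube(
    specs,
    shape: tuple[int, int] = (64, 64),
    background: float = 0.05,
    pixel_sigma: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
    layout=None,
) -> tuple[Hypercube, SeedMask, SpectrumTable]:
    """Render seeds with known spectra into a cube, with ground truth.

    ``specs`` is a sequence of :class:`VarietySpec`, one per seed; each
    seed is an ellipse filled with its own simulated mean spectrum plus
    optional per-pixel white noise of scale ``pixel_sigma``.  Returns the
    cube, the ground-truth mask (labels in raster order) and the table of
    true per-seed spectra.  Overlapping/touching layouts raise.
    """
    specs = list(specs)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = _auto_layout(len(specs), shape, rng)
    if len(layout) != len(specs):
        raise ValueError("layout length must match number of seeds")

    labels = np.zeros(shape, dtype=int)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    # raster order of centroids so labels match extraction order
    order = sorted(range(len(specs)), key=lambda k: (layout[k][0], layout[k][1]))
    spectra = np.empty((len(specs), len(grid)))
    names, cats = [], []
    for new_label, k in enumerate(order, start=1):
        cy, cx, ry, rx = layout[k]
        ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if not ellipse.any():
            raise ValueError(f"seed {k} footprint is empty")
        if (labels[ellipse] != 0).any():
            raise ValueError("seed footprints overlap")
        # require a 1-px clearance so regions stay disconnected
        dil = np.zeros(shape, dtype=bool)
        dil[ellipse] = True
        pad = (
            np.roll(dil, 1, 0) | np.roll(dil, -1, 0) | np.roll(dil, 1, 1) | np.roll(dil, -1, 1)
        )
        if (labels[pad & ~dil] != 0).any():
            raise ValueError("seed footprints touch")
        labels[ellipse] = new_label
        spec = specs[k]
        table = simulate_spectra(
            spec, 1, 1, grid=grid, seed=int(rng.integers(2**31)), category="unknown"
        )
        spectra[new_label - 1] = table.spectra[0]
        names.append(spec.name)
        cats.append("unknown")

    cube_data = np.full(shape + (len(grid),), background, dtype=float)
    for lab in range(1, len(specs) + 1):
        cube_data[labels == lab] = spectra[lab - 1]
    if pixel_sigma > 0:
        cube_data = cube_data + rng.normal(0.0, pixel_sigma, cube_data.shape)

    mask = SeedMask(labels, len(specs))
    meta = pd.DataFrame(
        {
            "category": cats,
            "variety": names,
            "lot": ["unknown"] * len(specs),
            "surface": ["unknown"] * len(specs),
        }
    )
    truth = SpectrumTable(spectra, grid, meta)
    cube = Hypercube(cube_data, grid, {"simulated": True, "background": background})
    return cube, mask, truth


# ---------------------------------------------------------------------------
# feature-table simulation
# ---------------------------------------------------------------------------

def simulate_feature_table(
    n_per_class: int = 315,
    effect: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a 54-feature table from per-class normals.

    ``effect`` maps feature names to between-category mean shifts (in SD
    units); unlisted features have zero shift, so their distributions
    overlap almost completely, mirroring mostly-uninformative seed
    morphometrics.
    """
    from .features import FEATURE_NAMES

    effect = effect or {}
    unknown = set(effect) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"effect names not in registry: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    shift = np.array([effect.get(name, 0.0) for name in FEATURE_NAMES])
    a = rng.standard_normal((n_per_class, len(FEATURE_NAMES)))
    b = rng.standard_normal((n_per_class, len(FEATURE_NAMES))) + shift
    table = pd.DataFrame(np.vstack([a, b]), columns=FEATURE_NAMES)
    table["category"] = ["target"] * n_per_class + ["non-target"] * n_per_class
    table["variety"] = table["category"]
    table["lot"] = "sim"
    table["surface"] = "unknown"
    return table


# ---------------------------------------------------------------------------
# study-scale scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Design of a two-category experiment.

    The defaults mirror the study design: nine target lots of 35 seeds
    versus nine non-target varieties of 35 seeds each, with per-variety
    divergences obtained by scaling a loci-like distance profile.  The
    loci-to-divergence mapping is a linear modeling convenience, not a
    biological claim.
    """

    n_target_lots: int = 9
    seeds_per_lot: int = 35
    nontarget_loci: tuple = (2, 3, 5, 5, 7, 8, 8, 8, 10)
    divergence_scale: float = 0.02
    lot_sigma: float = 0.008
    seed_sigma: float = 0.02
    grid_step_nm: float = 4.0
    surface: str = "mixed"
    seed: int = 0

    def divergences(self) -> tuple:
        return tuple(self.divergence_scale * n for n in self.nontarget_loci)


def simulate_scenario(cfg: ScenarioConfig) -> SpectrumTable:
    """Generate the pooled training table for a scenario."""
    grid = default_grid(cfg.grid_step_nm)
    target = target_variety_spec(
        "JK-target", lot_sigma=cfg.lot_sigma, seed_sigma=cfg.seed_sigma
    )
    rng = np.random.default_rng(cfg.seed)

    surfaces = ["germ", "non-germ"] if cfg.surface == "mixed" else [cfg.surface]
    tables = []
    for surface in surfaces:
        tables.append(
            simulate_spectra(
                target,
                cfg.n_target_lots,
                cfg.seeds_per_lot,
                grid=grid,
                seed=int(rng.integers(2**31)),
                category="target",
                surface=surface,
            )
        )
    for i, d in enumerate(cfg.divergences()):
        variety = make_variety_spec(
            target, d, seed=int(rng.integers(2**31)), name=f"nontarget-{i + 1}"
        )
        for surface in surfaces:
            tables.append(
                simulate_spectra(
                    variety,
                    1,
                    cfg.seeds_per_lot,
                    grid=grid,
                    seed=int(rng.integers(2**31)),
                    category="non-target",
                    surface=surface,
                )
            )
    return SpectrumTable.concat(tables)


def confusable_scenario(
    seed: int = 0,
    n_confusable: int = 3,
    shared_shift: float = 0.08,
    grid_step_nm: float = 4.0,
):
    """Training table + external verification set with confusable varieties.

    The external set holds two fresh target lots, two easy (far) non-target
    varieties and ``n_confusable`` varieties sharing one small spectral
    shift direction, so the initial model misreads all of them as the
    target; absorbing one should rescue the rest.  Returns
    ``(train_table, external_table)``.
    """
    rng = np.random.default_rng(seed)
    grid = default_grid(grid_step_nm)
    target = target_variety_spec("JK-target")
    tables = [
        simulate_spectra(
            target, 9, 35, grid=grid, seed=int(rng.integers(2**31)), category="target"
        )
    ]
    for i in range(4):  # well-separated training non-targets
        v = make_variety_spec(
            target, 0.20, seed=int(rng.integers(2**31)), name=f"train-nt-{i + 1}"
        )
        tables.append(
            simulate_spectra(
                v, 1, 35, grid=grid, seed=int(rng.integers(2**31)), category="non-target"
            )
        )
    train = SpectrumTable.concat(tables)

    ext = [
        simulate_spectra(
            target,
            2,
            35,
            grid=grid,
            seed=int(rng.integers(2**31)),
            category="target",
            lot_prefix="ext-target-lot",
        )
    ]
    # treat each external target lot as its own "variety" for reporting
    ext[0].meta["variety"] = list(ext[0].meta["lot"])
    for i in range(2):
        v = make_variety_spec(
            target, 0.25, seed=int(rng.integers(2**31)), name=f"ext-easy-{i + 1}"
        )
        ext.append(
            simulate_spectra(
                v, 1, 35, grid=grid, seed=int(rng.integers(2**31)), category="non-target"
            )
        )
    # confusable cluster: one shared direction, small magnitudes
    shared_seed = int(rng.integers(2**31))
    for i in range(n_confusable):
        v = make_variety_spec(
            target,
            shared_shift * (1.0 + 0.15 * i),
            seed=shared_seed,  # same direction for the whole cluster
            name=f"ext-confusable-{i + 1}",
        )
        ext.append(
            simulate_spectra(
                v, 1, 35, grid=grid, seed=int(rng.integers(2**31)), category="non-target"
            )
        )
    return train, SpectrumTable.concat(ext)


# minor absorption features spread across the spectrum; with the three
# main bands they give varietal divergence 13 degrees of freedom, more
# than a ~10-wavelength characteristic subset can span
_MINOR_BANDS = tuple(
    AbsorptionBand(c, 0.05, w)
    for c, w in [
        (430, 16), (490, 18), (540, 20), (580, 16), (660, 22),
        (700, 18), (760, 20), (820, 24), (880, 20), (940, 18),
    ]
)


def rich_target_spec(name: str = "JK-target", **overrides) -> VarietySpec:
    """Target signature with extra minor absorption bands (13 in total)."""
    base = target_variety_spec(name, **overrides)
    return replace(base, bands=base.bands + _MINOR_BANDS)


def generalization_scenario(
    seed: int = 0,
    grid_step_nm: float = 4.0,
    train_divergence: float = 0.15,
    ext_divergence: float = 0.12,
):
    """Out-of-training-variety verification stressing wavelength coverage.

    Varieties diverge along random directions in a 13-band depth space
    (see :func:`rich_target_spec`), so a ~10-wavelength characteristic
    subset cannot span the whole contrast space; external varieties
    diverging along fresh directions are then better recognised by
    full-spectrum models, which keep all the wavelength coverage learned
    from training.  Two fresh target lots are included so external
    accuracy is not a one-class statistic.  Returns
    ``(train_table, external_table)``.
    """
    rng = np.random.default_rng(seed)
    grid = default_grid(grid_step_nm)
    target = rich_target_spec(seed_sigma=0.02, noise_bandwidth_nm=12.0)

    tables = [
        simulate_spectra(
            target, 9, 35, grid=grid, seed=int(rng.integers(2**31)), category="target"
        )
    ]
    for i in range(9):
        v = make_variety_spec(
            target,
            train_divergence,
            seed=int(rng.integers(2**31)),
            name=f"train-nt-{i + 1}",
        )
        tables.append(
            simulate_spectra(
                v, 1, 35, grid=grid, seed=int(rng.integers(2**31)), category="non-target"
            )
        )
    train = SpectrumTable.concat(tables)

    ext = [
        simulate_spectra(
            target,
            2,
            35,
            grid=grid,
            seed=int(rng.integers(2**31)),
            category="target",
            lot_prefix="ext-target-lot",
        )
    ]
    ext[0].meta["variety"] = list(ext[0].meta["lot"])
    for i in range(4):
        v = make_variety_spec(
            target,
            ext_divergence,
            seed=int(rng.integers(2**31)),
            name=f"ext-nt-{i + 1}",
        )
        ext.append(
            simulate_spectra(
                v, 1, 35, grid=grid, seed=int(rng.integers(2**31)), category="non-target"
            )
        )
    return train, SpectrumTable.concat(ext)
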