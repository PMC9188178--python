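"""Machine-vision branch: 54 shape/colour/texture features per seed.

The registry is fixed: 14 shape, 24 colour and 16 texture descriptors
per segmented seed, extracted from an RGB scan and a label mask.  A
per-class distribution-overlap report summarises how informative each
feature is for the binary target / non-target decision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage.color import rgb2hsv
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from .segmentation import SeedMask

__all__ = [
    "SHAPE_FEATURES",
    "COLOR_FEATURES",
    "TEXTURE_FEATURES",
    "FEATURE_NAMES",
    "extract_seed_features",
    "feature_overlap_report",
]

SHAPE_FEATURES = [
    "area",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "eccentricity",
    "circularity",
    "solidity",
    "extent",
    "convex_area",
    "equivalent_diameter",
    "orientation",
    "bbox_width",
    "bbox_height",
]

_COLOR_CHANNELS = ["r", "g", "b", "h", "s", "v"]
_COLOR_STATS = ["mean", "std", "min", "max"]
COLOR_FEATURES = [f"{ch}_{st}" for ch in _COLOR_CHANNELS for st in _COLOR_STATS]

_GLCM_PROPS = ["contrast", "correlation", "energy", "homogeneity"]
_GLCM_ANGLES_DEG = [0, 45, 90, 135]
TEXTURE_FEATURES = [f"glcm_{p}_{a}" for p in _GLCM_PROPS for a in _GLCM_ANGLES_DEG]

FEATURE_NAMES = SHAPE_FEATURES + COLOR_FEATURES + TEXTURE_FEATURES
assert len(FEATURE_NAMES) == 54

# ITU-R 601 luma weights for the 8-bit grey conversion used by the GLCM
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_float_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    image = image[:, :, :3]
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    return image.astype(float)


def _shape_features(prop) -> dict:
    minr, minc, maxr, maxc = prop.bbox
    # Crofton estimator: less upward-biased on rasterized convex blobs
    perimeter = prop.perimeter_crofton
    perim = perimeter if perimeter > 0 else 1.0
    minor = prop.minor_axis_length
    return {
        "area": float(prop.area),
        "perimeter": float(perimeter),
        "major_axis_length": float(prop.major_axis_length),
        "minor_axis_length": float(minor),
        "aspect_ratio": float(prop.major_axis_length / minor) if minor > 0 else 1.0,
        "eccentricity": float(prop.eccentricity),
        "circularity": float(4.0 * np.pi * prop.area / perim**2),
        "solidity": float(prop.solidity),
        "extent": float(prop.extent),
        "convex_area": float(prop.area_convex),
        "equivalent_diameter": float(prop.equivalent_diameter_area),
        "orientation": float(prop.orientation),
        "bbox_width": float(maxc - minc),
        "bbox_height": float(maxr - minr),
    }


def _color_features(rgb_pixels: np.ndarray) -> dict:
    hsv_pixels = rgb2hsv(rgb_pixels[np.newaxis, :, :])[0]
    channels = {
        "r": rgb_pixels[:, 0],
        "g": rgb_pixels[:, 1],
        "b": rgb_pixels[:, 2],
        "h": hsv_pixels[:, 0],
        "s": hsv_pixels[:, 1],
        "v": hsv_pixels[:, 2],
    }
    out = {}
    for ch, vals in channels.items():
        out[f"{ch}_mean"] = float(vals.mean())
        out[f"{ch}_std"] = float(vals.std())
        out[f"{ch}_min"] = float(vals.min())
        out[f"{ch}_max"] = float(vals.max())
    return out


def _texture_features(gray_crop: np.ndarray, region_mask: np.ndarray) -> dict:
    # fill background with the region mean so GLCM pairs straddling the
    # boundary do not inject spurious contrast
    fill = gray_crop[region_mask].mean()
    crop = np.where(region_mask, gray_crop, fill)
    crop8 = np.clip(np.round(crop * 255), 0, 255).astype(np.uint8)
    angles = np.deg2rad(_GLCM_ANGLES_DEG)
    glcm = graycomatrix(
        crop8, distances=[1], angles=angles, levels=256, symmetric=True, normed=True
    )
    out = {}
    for p in _GLCM_PROPS:
        vals = graycoprops(glcm, p)[0]
        for a, v in zip(_GLCM_ANGLES_DEG, vals):
            out[f"glcm_{p}_{a}"] = float(v)
    return out


def extract_seed_features(
    image: np.ndarray, mask: SeedMask, labels_meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Extract the 54-feature registry for every seed in ``mask``.

    Seeds touching the image border are flagged in the ``touches_border``
    column but their features are still computed on the visible region.
    Returns one row per seed in ascending label order, with the 54
    feature columns followed by label/flag columns.
    """
    rgb = _to_float_rgb(image)
    if mask.labels.shape != rgb.shape[:2]:
        raise ValueError("mask not aligned to image")
    if labels_meta is not None and len(labels_meta) != mask.n_seeds:
        raise ValueError("annotation count != n_seeds")

    gray = rgb @ _LUMA
    h, w = mask.labels.shape
    rows = []
    flags = []
    for prop in sorted(regionprops(mask.labels), key=lambda p: p.label):
        feats = _shape_features(prop)
        region_pix = rgb[prop.coords[:, 0], prop.coords[:, 1], :]
        feats.update(_color_features(region_pix))
        minr, minc, maxr, maxc = prop.bbox
        feats.update(_texture_features(gray[minr:maxr, minc:maxc], prop.image))
        rows.append([feats[name] for name in FEATURE_NAMES])
        flags.append(bool(minr == 0 or minc == 0 or maxr == h or maxc == w))

    table = pd.DataFrame(rows, columns=FEATURE_NAMES)
    table["touches_border"] = flags
    if labels_meta is not None:
        table = pd.concat([table, labels_meta.reset_index(drop=True)], axis=1)
    return table


def _overlap_coefficient(a: np.ndarray, b: np.ndarray, n_grid: int = 512) -> float:
    """Integral of min of the two kernel-density estimates, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        # degenerate point masses: overlap only if both sit on the same point
        if a.std() == 0 and b.std() == 0:
            return 1.0 if a[0] == b[0] else 0.0
        return 0.0  # a point mass has measure zero under the diffuse density
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.2 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    da = gaussian_kde(a)(grid)
    db = gaussian_kde(b)(grid)
    return float(np.trapezoid(np.minimum(da, db), grid))


def feature_overlap_report(
    table: pd.DataFrame, category_col: str = "category"
) -> pd.DataFrame:
    """Per-feature distribution overlap between the two categories.

    For every registry feature present in ``table``, estimates a kernel
    density per category and reports the overlap coefficient (integral of
    the pointwise minimum of the two densities).  1.0 means the feature is
    uninformative; 0.0 means fully separated.
    """
    cats = table[category_col].unique()
    if len(cats) < 2:
        raise ValueError("overlap report requires both categories")
    if len(cats) > 2:
        raise ValueError(f"expected exactly 2 categories, found {list(cats)}")

    group_of = {}
    for name in SHAPE_FEATURES:
        group_of[name] = "shape"
    for name in COLOR_FEATURES:
        group_of[name] = "color"
    for name in TEXTURE_FEATURES:
        group_of[name] = "texture"

    a_rows = table[table[category_col] == cats[0]]
    b_rows = table[table[category_col] == cats[1]]
    records = []
    for name in FEATURE_NAMES:
        if name not in table.columns:
            continue
        ovl = _overlap_coefficient(a_rows[name].to_numpy(), b_rows[name].to_numpy())
        records.append({"feature": name, "group": group_of[name], "overlap": ovl})
    return pd.DataFrame(records)
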