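"""Seed segmentation and per-seed mean-spectrum extraction.

A cube is reduced to a single grayscale image, thresholded (Otsu by
default), connected components below a minimum area are discarded, and
the surviving regions are renumbered in raster order of their centroids
so that label k always refers to the k-th seed in reading order.  One
mean reflectance spectrum is then extracted per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .hsi import Hypercube

__all__ = ["SeedMask", "SpectrumTable", "threshold_mask", "extract_mean_spectra"]

LABEL_COLUMNS = ["category", "variety", "lot", "surface"]


@dataclass
class SeedMask:
    """Integer label image: 0 = background, 1..n_seeds = seed regions."""

    labels: np.ndarray
    n_seeds: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        present = np.unique(self.labels)
        expected = np.arange(0, self.n_seeds + 1)
        present_nonzero = present[present != 0]
        if not np.array_equal(present_nonzero, np.arange(1, self.n_seeds + 1)):
            raise ValueError(
                f"labels must be contiguous 1..{self.n_seeds}, found {present_nonzero}"
            )


@dataclass
class SpectrumTable:
    """Per-seed mean spectra plus category/variety/lot/surface annotations.

    ``spectra`` is ``(n_seeds, n_bands)``; ``meta`` is a DataFrame with at
    least the columns in :data:`LABEL_COLUMNS`, one row per seed, aligned
    with the rows of ``spectra``.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.shape[1] != len(self.wavelengths):
            raise ValueError("spectrum length must equal wavelength count")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")
        if len(self.meta) != self.spectra.shape[0]:
            raise ValueError(
                f"annotation count {len(self.meta)} != seed count {self.spectra.shape[0]}"
            )
        missing = [c for c in LABEL_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing label columns: {missing}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Binary response: 1 for the target category, 0 otherwise."""
        return (self.meta["category"].to_numpy() == "target").astype(int)

    def select(self, mask) -> "SpectrumTable":
        mask = np.asarray(mask)
        return SpectrumTable(
            self.spectra[mask], self.wavelengths.copy(), self.meta.iloc[mask].copy()
        )

    def select_bands(self, band_idx) -> "SpectrumTable":
        band_idx = np.asarray(band_idx, dtype=int)
        return SpectrumTable(
            self.spectra[:, band_idx], self.wavelengths[band_idx], self.meta.copy()
        )

    @staticmethod
    def concat(tables: list["SpectrumTable"]) -> "SpectrumTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        wl = tables[0].wavelengths
        for t in tables[1:]:
            if not np.array_equal(t.wavelengths, wl):
                raise ValueError("wavelength grids differ")
        return SpectrumTable(
            np.vstack([t.spectra for t in tables]),
            wl.copy(),
            pd.concat([t.meta for t in tables], ignore_index=True),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.spectra, columns=[f"wl_{w:g}" for w in self.wavelengths]
        )
        out = pd.concat([df, self.meta.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "SpectrumTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        meta = df[[c for c in df.columns if not c.startswith("wl_")]]
        return SpectrumTable(df[wl_cols].to_numpy(dtype=float), wavelengths, meta)


def _reduce_to_image(cube: Hypercube, band_reduce: str, band: int | None) -> np.ndarray:
    if band_reduce == "mean":
        return cube.data.mean(axis=2)
    if band_reduce == "single-band":
        if band is None:
            raise ValueError("band_reduce='single-band' requires a band index")
        return cube.data[:, :, band]
    raise ValueError(f"unknown band_reduce {band_reduce!r}")


def threshold_mask(
    cube: Hypercube,
    method: str = "otsu",
    band_reduce: str = "mean",
    band: int | None = None,
    threshold: float | None = None,
    min_area: int = 50,
    connectivity: int = 8,
) -> SeedMask:
    """Threshold-segment a cube into seed regions.

    ``method='otsu'`` thresholds the band-reduced image automatically;
    ``method='fixed'`` uses ``threshold``.  Components with fewer than
    ``min_area`` pixels are discarded and the remaining regions are
    renumbered contiguously in raster order of their centroids.
    """
    img = _reduce_to_image(cube, band_reduce, band)
    if method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("constant image: no foreground found", stacklevel=2)
            return SeedMask(np.zeros(img.shape, dtype=int), 0)
        thr = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}")

    fg = img > thr
    if not fg.any():
        warnings.warn("no foreground pixel above threshold", stacklevel=2)
        return SeedMask(np.zeros(img.shape, dtype=int), 0)

    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = cc_label(fg, connectivity=1 if connectivity == 4 else 2)

    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts >= min_area)
    keep = keep[keep != 0]
    if keep.size == 0:
        warnings.warn("all regions below min_area", stacklevel=2)
        return SeedMask(np.zeros(img.shape, dtype=int), 0)

    # renumber kept regions in raster order of centroid (row-major)
    centroids = ndimage.center_of_mass(fg, lab, keep)
    order = sorted(range(len(keep)), key=lambda i: (centroids[i][0], centroids[i][1]))
    remap = np.zeros(lab.max() + 1, dtype=int)
    for new, i in enumerate(order, start=1):
        remap[keep[i]] = new
    return SeedMask(remap[lab], len(keep))


def extract_mean_spectra(
    cube: Hypercube,
    mask: SeedMask,
    labels_meta: pd.DataFrame | None = None,
) -> SpectrumTable:
    """Average the cube over each seed region, one spectrum per seed.

    Row order follows ascending label (raster order by construction of
    :func:`threshold_mask`).  ``labels_meta``, when given, must hold one
    annotation row per seed.
    """
    if mask.labels.shape != cube.spatial_shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} != cube spatial shape {cube.spatial_shape}"
        )
    if labels_meta is not None and len(labels_meta) != mask.n_seeds:
        raise ValueError(
            f"annotation count {len(labels_meta)} != n_seeds {mask.n_seeds}"
        )

    idx = np.arange(1, mask.n_seeds + 1)
    spectra = np.empty((mask.n_seeds, cube.n_bands))
    flat_labels = mask.labels
    for b in range(cube.n_bands):
        spectra[:, b] = ndimage.mean(cube.data[:, :, b], labels=flat_labels, index=idx)

    if labels_meta is None:
        labels_meta = pd.DataFrame(
            {
                "category": ["unknown"] * mask.n_seeds,
                "variety": ["unknown"] * mask.n_seeds,
                "lot": ["unknown"] * mask.n_seeds,
                "surface": ["unknown"] * mask.n_seeds,
            }
        )
    return SpectrumTable(spectra, cube.wavelengths.copy(), labels_meta.copy())
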