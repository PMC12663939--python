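"""Pixel-level FRET → water-potential mapping and cell morphometrics.

A FRET-based nanoreporter coating the cell walls of the outside-xylem zone
reports local water potential through its FRET efficiency ζ.  Given a 2D
ζ map, a monotone calibration curve ζ(ψ) and an autofluorescence channel,
this module

* inverts the calibration pixel-wise to a ψ map (MPa),
* summarizes the masked ψ distribution by a fixed-bin-width histogram and
  its mode, and
* segments cells in the autofluorescence channel and measures area,
  perimeter and circularity (4πA/P²), with a one-way ANOVA + Tukey HSD
  group comparison.

The calibration curve is injected configuration — it is never derived
here.  The shipped :data:`DEFAULT_CALIBRATION` is a synthetic placeholder
logistic spanning [−20, 0] MPa for testing only, not a physiological
calibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from skimage import filters, measure, morphology, segmentation
import scipy.ndimage as ndi

__all__ = [
    "CalibrationCurve",
    "DEFAULT_CALIBRATION",
    "FretImage",
    "CellMorphology",
    "zeta_to_psi_map",
    "psi_histogram",
    "cell_morphometrics",
    "group_compare",
]

logger = logging.getLogger(__name__)


class CalibrationCurve:
    """Strictly monotone map between FRET efficiency ζ and water potential ψ.

    Parametric form (logistic, decreasing in ψ — the reporter's FRET
    efficiency rises as the hydrogel dehydrates and collapses):

        ζ(ψ) = ζ_wet + (ζ_dry − ζ_wet) / (1 + exp((ψ − ψ50)/slope))

    or a tabulated (ψ, ζ) curve interpolated monotonically
    (:meth:`from_table`).  Valid over ``psi_range`` (MPa); pixels mapping
    outside it are flagged as missing.
    """

    def __init__(self, zeta_wet: float = 0.20, zeta_dry: float = 0.70,
                 psi_50: float = -8.0, slope: float = 3.0,
                 psi_range: tuple[float, float] = (-20.0, 0.0)):
        if not zeta_dry > zeta_wet:
            raise ValueError("require zeta_dry > zeta_wet")
        if slope <= 0:
            raise ValueError("slope must be positive")
        self.zeta_wet = zeta_wet
        self.zeta_dry = zeta_dry
        self.psi_50 = psi_50
        self.slope = slope
        self.psi_range = (min(psi_range), max(psi_range))
        self._table = None

    @classmethod
    def from_table(cls, psi: Sequence[float], zeta: Sequence[float]) -> "CalibrationCurve":
        """Build a calibration from tabulated (ψ, ζ) pairs (PCHIP interpolation)."""
        psi = np.asarray(psi, float)
        zeta = np.asarray(zeta, float)
        order = np.argsort(psi)
        psi, zeta = psi[order], zeta[order]
        d = np.diff(zeta)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("calibration table must be strictly monotone")
        obj = cls(psi_range=(float(psi[0]), float(psi[-1])))
        obj._table = (PchipInterpolator(psi, zeta),
                      PchipInterpolator(zeta if d[0] > 0 else zeta[::-1],
                                        psi if d[0] > 0 else psi[::-1]))
        obj._zeta_bounds = (float(zeta.min()), float(zeta.max()))
        return obj

    def zeta(self, psi):
        """ζ(ψ)."""
        p = np.asarray(psi, float)
        if self._table is not None:
            out = self._table[0](p)
        else:
            out = self.zeta_wet + (self.zeta_dry - self.zeta_wet) / (
                1.0 + np.exp(np.clip((p - self.psi_50) / self.slope, -500, 500)))
        return out if np.ndim(out) else float(out)

    def psi(self, zeta):
        """Inverse map ψ(ζ); values outside the calibrated ζ range give NaN."""
        z = np.asarray(zeta, float)
        if self._table is not None:
            lo, hi = self._zeta_bounds
            out = np.where((z >= lo) & (z <= hi), self._table[1](np.clip(z, lo, hi)), np.nan)
        else:
            zlo = self.zeta(self.psi_range[1])   # wet end (least negative psi)
            zhi = self.zeta(self.psi_range[0])   # dry end
            lo, hi = min(zlo, zhi), max(zlo, zhi)
            with np.errstate(divide="ignore", invalid="ignore"):
                arg = (self.zeta_dry - z) / (z - self.zeta_wet)
                psi = self.psi_50 + self.slope * np.log(arg)
            out = np.where((z > lo) & (z < hi), psi, np.nan)
        return out if np.ndim(out) else float(out)

    def __call__(self, psi):
        return self.zeta(psi)


#: Synthetic placeholder calibration for tests and demos — NOT physiological.
DEFAULT_CALIBRATION = CalibrationCurve()


@dataclass
class FretImage:
    """A FRET-efficiency map with its autofluorescence channel.

    ``zeta_map`` and ``autofluorescence`` must share a shape; ``pixel_size``
    in µm; ``metadata`` may carry a condition label and the bulk reference
    water potential of the tissue.
    """

    zeta_map: np.ndarray
    autofluorescence: np.ndarray
    pixel_size: float = 1.0
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zeta_map = np.asarray(self.zeta_map, float)
        self.autofluorescence = np.asarray(self.autofluorescence, float)
        if self.zeta_map.shape != self.autofluorescence.shape:
            raise ValueError("zeta_map and autofluorescence shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def zeta_to_psi_map(img: FretImage, cal: CalibrationCurve) -> np.ndarray:
    """Pixel-wise inversion of the calibration: ζ map → ψ map (MPa).

    Out-of-range pixels become NaN; their count is logged.
    """
    psi = cal.psi(img.zeta_map)
    n_bad = int(np.sum(np.isnan(psi)) - np.sum(np.isnan(img.zeta_map)))
    if n_bad > 0:
        logger.warning("%d pixel(s) outside the calibration range", n_bad)
    return psi


def psi_histogram(psi_map: np.ndarray, bin_width: float = 0.25,
                  mask: np.ndarray | None = None):
    """Histogram of pixel-level water potentials and its mode.

    Bins are fixed-width, aligned to integer multiples of ``bin_width``;
    the mode is the center of the tallest bin, ties resolved toward the
    less negative bin.  Requires at least 100 valid pixels.

    Returns ``(hist, mode)`` where ``hist`` is a DataFrame with columns
    ``bin_center_MPa`` and ``count``.
    """
    x = np.asarray(psi_map, float)
    if mask is not None:
        x = x[np.asarray(mask, bool)]
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError(f"only {x.size} valid pixels (need >= 100)")
    # bins centered on integer multiples of bin_width, so a constant field
    # reports its own value as the mode
    k_lo = math.floor(x.min() / bin_width + 0.5)
    k_hi = math.floor(x.max() / bin_width + 0.5)
    edges = (np.arange(k_lo, k_hi + 2) - 0.5) * bin_width
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = np.flatnonzero(counts == counts.max())[-1]   # ties: less negative
    hist = pd.DataFrame({"bin_center_MPa": centers, "count": counts})
    return hist, float(centers[best])


@dataclass(frozen=True)
class CellMorphology:
    """Morphometrics of one segmented cell (area µm², perimeter µm)."""

    label: int
    area: float
    perimeter: float
    circularity: float


def _contour_metrics(mask: np.ndarray, sigma: float = 1.0):
    """Perimeter and area from a Gaussian-smoothed marching-squares contour.

    Smoothing the binary mask (σ = 1 px) before contouring removes the
    pixel staircase that would otherwise bias the perimeter high (a raw
    contour of a disk reads ~5 % long).  Area is the shoelace area of the
    same contour, so both come from one consistent boundary.
    """
    f = filters.gaussian(np.pad(mask.astype(float), 2), sigma=sigma)
    contours = measure.find_contours(f, 0.5)
    if not contours:
        return 0.0, 0.0
    c = max(contours, key=lambda c: c.shape[0])
    d = np.diff(c, axis=0)
    perim = float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    x, y = c[:, 1], c[:, 0]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return perim, float(area)


def segment_cells(autofluorescence: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Label cells in an autofluorescence image.

    Otsu threshold → hole filling → small-object removal → distance-transform
    watershed to split touching cells → border-touching labels dropped.
    """
    img = np.asarray(autofluorescence, float)
    thr = filters.threshold_otsu(img)
    fg = ndi.binary_fill_holes(img > thr)
    comp, n_comp = ndi.label(fg)
    if n_comp:
        sizes = np.bincount(comp.ravel())
        keep = np.flatnonzero(sizes >= min_area)
        fg = np.isin(comp, keep[keep != 0])
    if not fg.any():
        return np.zeros(img.shape, dtype=int)
    dist = ndi.distance_transform_edt(fg)
    peaks = morphology.h_maxima(dist, 2.0)
    markers, _ = ndi.label(peaks)
    labels = segmentation.watershed(-dist, markers, mask=fg)
    labels = segmentation.clear_border(labels)
    return labels


def cell_morphometrics(autofluorescence: np.ndarray,
                       masks: np.ndarray | None = None,
                       pixel_size: float = 1.0,
                       min_area: int = 50) -> list[CellMorphology]:
    """Area, perimeter and circularity (4πA/P², capped at 1) per cell.

    Segments the autofluorescence channel unless a label image is supplied;
    cells touching the image border are excluded.
    """
    labels = segment_cells(autofluorescence, min_area) if masks is None \
        else segmentation.clear_border(np.asarray(masks, int))
    out: list[CellMorphology] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        sub = labels[region.slice] == region.label
        perim_px, area_px = _contour_metrics(sub)
        if perim_px <= 0:
            continue
        circ = min(4.0 * math.pi * area_px / perim_px ** 2, 1.0)
        out.append(CellMorphology(
            label=int(region.label),
            area=area_px * pixel_size ** 2,
            perimeter=perim_px * pixel_size,
            circularity=circ,
        ))
    if not out:
        logger.warning("no segmentable cells found")
    return out


def group_compare(groups: Mapping[str, Sequence[CellMorphology]],
                  metrics: Sequence[str] = ("area", "circularity"),
                  alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD across conditions, per morphometric.

    Returns a long table with one row per (metric, pair): mean difference,
    adjusted p-value, significance flag, plus compact letters per group in
    the attached ``attrs['letters']`` mapping.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if len(groups[name]) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 cells")

    rows = []
    letters: dict[str, dict[str, str]] = {}
    for metric in metrics:
        values = np.concatenate([
            np.array([getattr(c, metric) for c in groups[g]], float) for g in names])
        labels = np.concatenate([np.repeat(g, len(groups[g])) for g in names])
        if np.allclose(values.std(), 0):
            logger.warning("degenerate (zero-variance) metric %s", metric)
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    rows.append({"metric": metric, "group1": names[a],
                                 "group2": names[b], "meandiff": 0.0,
                                 "p_adj": 1.0, "significant": False})
            letters[metric] = {g: "a" for g in names}
            continue
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        for _, r in tbl.iterrows():
            rows.append({"metric": metric, "group1": r["group1"],
                         "group2": r["group2"], "meandiff": float(r["meandiff"]),
                         "p_adj": float(r["p-adj"]), "significant": bool(r["reject"])})
        letters[metric] = _compact_letters(
            names,
            {(r["group1"], r["group2"]): bool(r["reject"]) for _, r in tbl.iterrows()})
    out = pd.DataFrame(rows)
    out.attrs["letters"] = letters
    return out


def _compact_letters(names: Sequence[str], significant: Mapping[tuple, bool]) -> dict:
    """Greedy compact-letter display: groups share a letter iff no pair among
    them differs significantly."""
    def differs(a, b):
        return significant.get((a, b), significant.get((b, a), False))

    sets: list[set] = []
    for g in names:
        placed = False
        for s in sets:
            if all(not differs(g, h) for h in s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    # drop subsets, keep insertion order
    sets = [s for i, s in enumerate(sets)
            if not any(s < t for j, t in enumerate(sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {g: "".join(alphabet[i] for i, s in enumerate(sets) if g in s)
            for g in names}
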