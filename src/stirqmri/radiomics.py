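"""LIFEx-compatible radiomic feature catalog: 25 first-order, 26
second-order (7 GLCM + 11 GLZLM + 8 GLRLM) and 5 shape features per
muscle ROI, averaged over left and right sides.

Conventions (documented because they change numbers):

* Quantization: G = 64 gray levels with LIFEx-style relative bounds,
  ``level = 1 + floor(G * (x - min) / (max - min + 1))`` clipped to
  [1, G]; a constant ROI maps entirely to level 1.
* Quantiles: linear interpolation between order statistics (type 7);
  variance and SD are population (divide by n).
* GLCM: distance 1, four 2D directions (0, 45, 90, 135 degrees),
  symmetric; the per-direction normalized matrices are averaged before
  feature computation.
* GLZLM zones: 8-connected flat zones.
* GLRLM: per-direction normalized features averaged over the four
  directions (so run percentage stays in (0, 1]).
* Shape: perimeter is the boundary-edge count (pixel edges facing
  background) times the pixel spacing.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantoms import MUSCLES, SIDES, RoiMaskSet, SliceImage, Subject

logger = logging.getLogger(__name__)

#: default gray-level count for texture quantization
DEFAULT_GRAY_LEVELS = 64

#: GLCM offsets (dy, dx) for 0, 90, 45, 135 degrees at distance 1
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

FIRST_ORDER_NAMES = (
    "CONVENTIONAL_min", "CONVENTIONAL_max", "CONVENTIONAL_range",
    "CONVENTIONAL_mean", "CONVENTIONAL_std", "CONVENTIONAL_variance",
    "CONVENTIONAL_CoV", "CONVENTIONAL_skewness", "CONVENTIONAL_kurtosis",
    "CONVENTIONAL_ExcessKurtosis", "CONVENTIONAL_Q1", "CONVENTIONAL_median",
    "CONVENTIONAL_Q3", "CONVENTIONAL_IQR", "CONVENTIONAL_P10",
    "CONVENTIONAL_P90", "CONVENTIONAL_HistogramMode", "CONVENTIONAL_sum",
    "CONVENTIONAL_RMS", "CONVENTIONAL_MAD", "CONVENTIONAL_RobustMAD",
    "CONVENTIONAL_Entropy_log2", "CONVENTIONAL_Entropy_log10",
    "CONVENTIONAL_Uniformity", "CONVENTIONAL_Energy",
)
GLCM_NAMES = (
    "GLCM_Homogeneity", "GLCM_Energy", "GLCM_Contrast", "GLCM_Correlation",
    "GLCM_Entropy_log10", "GLCM_Entropy_log2", "GLCM_Dissimilarity",
)
GLZLM_NAMES = (
    "GLZLM_SZE", "GLZLM_LZE", "GLZLM_LGZE", "GLZLM_HGZE", "GLZLM_SZLGE",
    "GLZLM_SZHGE", "GLZLM_LZLGE", "GLZLM_LZHGE", "GLZLM_GLNU", "GLZLM_ZLNU",
    "GLZLM_ZP",
)
GLRLM_NAMES = (
    "GLRLM_SRE", "GLRLM_LRE", "GLRLM_LGRE", "GLRLM_HGRE", "GLRLM_SRHGE",
    "GLRLM_GLNU", "GLRLM_RLNU", "GLRLM_RP",
)
SHAPE_NAMES = (
    "SHAPE_Volume_vx", "SHAPE_Volume_mL", "SHAPE_Surface_mm2",
    "SHAPE_Sphericity", "SHAPE_Compacity",
)

#: the full 56-name catalog: 25 first-order + 26 second-order + 5 shape
FEATURE_CATALOG = FIRST_ORDER_NAMES + GLCM_NAMES + GLZLM_NAMES + GLRLM_NAMES \
    + SHAPE_NAMES
assert len(FEATURE_CATALOG) == 56


def load_catalog() -> dict:
    """Load the versioned JSON feature catalog shipped with the package."""
    with resources.files("stirqmri").joinpath("data/feature_catalog.json"
                                              ).open() as fh:
        return json.load(fh)


@dataclass
class QuantizedRoi:
    """ROI gray levels on a spatial grid; 0 is the background sentinel."""

    grid: np.ndarray            # (H, W) int, 0 outside ROI, 1..G inside
    n_levels: int
    bin_edges: np.ndarray       # (G + 1,) original-intensity bounds

    @property
    def roi_mask(self) -> np.ndarray:
        return self.grid > 0

    def bin_center(self, level: int) -> float:
        return float(0.5 * (self.bin_edges[level - 1] + self.bin_edges[level]))


def quantize(image: np.ndarray, mask: np.ndarray,
             n_levels: int = DEFAULT_GRAY_LEVELS) -> QuantizedRoi:
    """Quantize in-ROI intensities to 1..G with LIFEx-style relative bounds.

    ``level = 1 + floor(G * (x - min) / (max - min + 1))``, clipped to
    [1, G]; a constant ROI maps to level 1 everywhere.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = np.asarray(image, dtype=np.float64)[mask]
    lo, hi = float(vals.min()), float(vals.max())
    grid = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        grid[mask] = 1
        width = 1.0 / n_levels
    else:
        width = (hi - lo + 1.0) / n_levels
        lev = 1 + np.floor((vals - lo) / width).astype(np.int64)
        grid[mask] = np.clip(lev, 1, n_levels)
    edges = lo + width * np.arange(n_levels + 1)
    return QuantizedRoi(grid=grid, n_levels=n_levels, bin_edges=edges)


# ---------------------------------------------------------------------------
# first-order features

def first_order_features(image: np.ndarray, mask: np.ndarray,
                         qroi: QuantizedRoi | None = None,
                         n_levels: int = DEFAULT_GRAY_LEVELS,
                         ) -> dict[str, float]:
    """The 25 intensity-distribution features.

    Entropies and uniformity are computed on the quantized histogram; all
    other statistics use raw intensities. Skewness/kurtosis of a constant
    ROI are defined as 0 (and excess kurtosis 0); CoV of a zero-mean ROI
    is defined as 0 so every value stays finite.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(image, dtype=np.float64)[mask]
    if vals.size < 2:
        raise ValueError("ROI must contain >= 2 pixels")
    if qroi is None:
        qroi = quantize(image, mask, n_levels)
    mean = float(vals.mean())
    var = float(vals.var())           # population
    std = float(np.sqrt(var))
    q1, med, q3, p10, p90 = np.quantile(vals, [0.25, 0.5, 0.75, 0.10, 0.90])
    if var > 0:
        z = (vals - mean) / std
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    else:
        skew, kurt = 0.0, 3.0
    levels = qroi.grid[mask]
    counts = np.bincount(levels, minlength=qroi.n_levels + 1)[1:]
    p = counts[counts > 0] / vals.size
    mode_level = int(np.argmax(counts)) + 1          # tie -> lowest level
    band = vals[(vals >= p10) & (vals <= p90)]
    robust_mad = float(np.abs(band - band.mean()).mean()) if band.size else 0.0
    return {
        "CONVENTIONAL_min": float(vals.min()),
        "CONVENTIONAL_max": float(vals.max()),
        "CONVENTIONAL_range": float(vals.max() - vals.min()),
        "CONVENTIONAL_mean": mean,
        "CONVENTIONAL_std": std,
        "CONVENTIONAL_variance": var,
        "CONVENTIONAL_CoV": std / mean if mean != 0 else 0.0,
        "CONVENTIONAL_skewness": skew,
        "CONVENTIONAL_kurtosis": kurt,
        "CONVENTIONAL_ExcessKurtosis": kurt - 3.0,
        "CONVENTIONAL_Q1": float(q1),
        "CONVENTIONAL_median": float(med),
        "CONVENTIONAL_Q3": float(q3),
        "CONVENTIONAL_IQR": float(q3 - q1),
        "CONVENTIONAL_P10": float(p10),
        "CONVENTIONAL_P90": float(p90),
        "CONVENTIONAL_HistogramMode": qroi.bin_center(mode_level),
        "CONVENTIONAL_sum": float(vals.sum()),
        "CONVENTIONAL_RMS": float(np.sqrt(np.mean(vals ** 2))),
        "CONVENTIONAL_MAD": float(np.abs(vals - mean).mean()),
        "CONVENTIONAL_RobustMAD": robust_mad,
        "CONVENTIONAL_Entropy_log2": float(-(p * np.log2(p)).sum()),
        "CONVENTIONAL_Entropy_log10": float(-(p * np.log10(p)).sum()),
        "CONVENTIONAL_Uniformity": float((p ** 2).sum()),
        "CONVENTIONAL_Energy": float((vals ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(qroi: QuantizedRoi,
                offsets: Sequence[tuple[int, int]] = GLCM_OFFSETS,
                ) -> np.ndarray:
    """Direction-averaged symmetric normalized co-occurrence matrix.

    Each offset's symmetric count matrix (pairs where both pixels are in
    the ROI) is normalized to sum 1, then the normalized matrices are
    averaged over the offsets that contain at least one pair.
    """
    g = qroi.grid
    G = qroi.n_levels
    mats = []
    h, w = g.shape
    for dy, dx in offsets:
        a = g[max(0, -dy):h - max(0, dy), max(0, -dx):w - max(0, dx)]
        b = g[max(0, dy):h - max(0, -dy), max(0, dx):w - max(0, -dx)]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ai, bi = a[valid] - 1, b[valid] - 1
        m = np.zeros((G, G))
        np.add.at(m, (ai, bi), 1.0)
        np.add.at(m, (bi, ai), 1.0)
        mats.append(m / m.sum())
    if not mats:
        raise ValueError("no valid pixel pair for any GLCM direction")
    return np.mean(mats, axis=0)


def glcm_features(qroi: QuantizedRoi,
                  offsets: Sequence[tuple[int, int]] = GLCM_OFFSETS,
                  ) -> dict[str, float]:
    """The 7 co-occurrence features on the direction-averaged matrix.

    Correlation of a single-gray-level (degenerate) matrix is defined
    as 0: no linear co-dependence is measurable.
    """
    p = glcm_matrix(qroi, offsets)
    G = p.shape[0]
    i = np.arange(1, G + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)
    nz = p > 0
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    sd_i = float(np.sqrt((((ii - mu_i) ** 2) * p).sum()))
    sd_j = float(np.sqrt((((jj - mu_j) ** 2) * p).sum()))
    if sd_i > 0 and sd_j > 0:
        corr = float((((ii - mu_i) * (jj - mu_j) * p).sum()) / (sd_i * sd_j))
    else:
        corr = 0.0
    return {
        "GLCM_Homogeneity": float((p / (1.0 + diff)).sum()),
        "GLCM_Energy": float((p ** 2).sum()),
        "GLCM_Contrast": float((diff ** 2 * p).sum()),
        "GLCM_Correlation": corr,
        "GLCM_Entropy_log10": float(-(p[nz] * np.log10(p[nz])).sum()),
        "GLCM_Entropy_log2": float(-(p[nz] * np.log2(p[nz])).sum()),
        "GLCM_Dissimilarity": float((diff * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLZLM (size-zone) and GLRLM (run-length)

_EIGHT = np.ones((3, 3), dtype=int)


def glzlm_matrix(qroi: QuantizedRoi) -> np.ndarray:
    """Gray level size-zone matrix: rows gray level 1..G, columns zone
    size 1..Z, entries zone counts (8-connected flat zones)."""
    g = qroi.grid
    G = qroi.n_levels
    zones: list[tuple[int, int]] = []       # (level, size)
    for level in range(1, G + 1):
        lab, n = ndimage.label(g == level, structure=_EIGHT)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    if not zones:
        raise ValueError("empty ROI")
    zmax = max(s for _, s in zones)
    m = np.zeros((G, zmax))
    for level, s in zones:
        m[level - 1, s - 1] += 1
    return m


def _zone_stats(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    G, Z = m.shape
    nz = float(m.sum())
    i = np.arange(1, G + 1, dtype=np.float64)[:, None]
    s = np.arange(1, Z + 1, dtype=np.float64)[None, :]
    return {
        "GLZLM_SZE": float((m / s ** 2).sum() / nz),
        "GLZLM_LZE": float((m * s ** 2).sum() / nz),
        "GLZLM_LGZE": float((m / i ** 2).sum() / nz),
        "GLZLM_HGZE": float((m * i ** 2).sum() / nz),
        "GLZLM_SZLGE": float((m / (i ** 2 * s ** 2)).sum() / nz),
        "GLZLM_SZHGE": float((m * i ** 2 / s ** 2).sum() / nz),
        "GLZLM_LZLGE": float((m * s ** 2 / i ** 2).sum() / nz),
        "GLZLM_LZHGE": float((m * i ** 2 * s ** 2).sum() / nz),
        "GLZLM_GLNU": float((m.sum(axis=1) ** 2).sum() / nz),
        "GLZLM_ZLNU": float((m.sum(axis=0) ** 2).sum() / nz),
        "GLZLM_ZP": float(nz / n_pixels),
    }


def glzlm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """The 11 size-zone features (standard GLSZM formulas)."""
    m = glzlm_matrix(qroi)
    return _zone_stats(m, int(qroi.roi_mask.sum()))


def _runs_along(line: np.ndarray) -> Iterable[tuple[int, int]]:
    """Run-length encode one line of gray levels; 0 breaks runs."""
    start = 0
    n = len(line)
    while start < n:
        level = line[start]
        end = start + 1
        while end < n and line[end] == level:
            end += 1
        if level > 0:
            yield int(level), end - start
        start = end


def _grid_lines(g: np.ndarray, direction: tuple[int, int]):
    h, w = g.shape
    if direction == (0, 1):
        yield from g
    elif direction == (1, 0):
        yield from g.T
    elif direction == (1, 1):
        for off in range(-h + 1, w):
            yield np.diagonal(g, offset=off)
    elif direction == (1, -1):
        gf = np.fliplr(g)
        for off in range(-h + 1, w):
            yield np.diagonal(gf, offset=off)
    else:                                     # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")


def glrlm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """The 8 run-length features, averaged over the four directions.

    Features are computed per direction on that direction's run matrix
    and then averaged, so run percentage (RP) remains in (0, 1].
    """
    g = qroi.grid
    G = qroi.n_levels
    n_pixels = int(qroi.roi_mask.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI")
    per_dir = []
    for direction in GLCM_OFFSETS:
        runs: list[tuple[int, int]] = []
        for line in _grid_lines(g, direction):
            runs.extend(_runs_along(np.asarray(line)))
        rmax = max(l for _, l in runs)
        m = np.zeros((G, rmax))
        for level, l in runs:
            m[level - 1, l - 1] += 1
        nr = float(m.sum())
        i = np.arange(1, G + 1, dtype=np.float64)[:, None]
        l = np.arange(1, rmax + 1, dtype=np.float64)[None, :]
        per_dir.append({
            "GLRLM_SRE": (m / l ** 2).sum() / nr,
            "GLRLM_LRE": (m * l ** 2).sum() / nr,
            "GLRLM_LGRE": (m / i ** 2).sum() / nr,
            "GLRLM_HGRE": (m * i ** 2).sum() / nr,
            "GLRLM_SRHGE": (m * i ** 2 / l ** 2).sum() / nr,
            "GLRLM_GLNU": (m.sum(axis=1) ** 2).sum() / nr,
            "GLRLM_RLNU": (m.sum(axis=0) ** 2).sum() / nr,
            "GLRLM_RP": nr / n_pixels,
        })
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# shape

def shape_features(mask: np.ndarray, pixel_spacing: float,
                   slice_thickness: float) -> dict[str, float]:
    """The 5 size/geometry features of a 2D mask extruded to the slice
    thickness.

    The in-plane perimeter is the boundary-edge count (pixel edges facing
    background) scaled by the pixel spacing. Sphericity and compactness
    use the extruded slab's total surface (lateral + both faces).
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    s, t = float(pixel_spacing), float(slice_thickness)
    pairs_h = int((mask[:, 1:] & mask[:, :-1]).sum())
    pairs_v = int((mask[1:, :] & mask[:-1, :]).sum())
    perimeter_mm = (4 * n - 2 * (pairs_h + pairs_v)) * s
    area_mm2 = n * s * s
    volume_mm3 = area_mm2 * t
    surface_total = perimeter_mm * t + 2.0 * area_mm2
    sphericity = (np.pi ** (1 / 3)) * (6.0 * volume_mm3) ** (2 / 3) \
        / surface_total
    compacity = volume_mm3 / (np.sqrt(np.pi) * surface_total ** 1.5)
    return {
        "SHAPE_Volume_vx": float(n),
        "SHAPE_Volume_mL": volume_mm3 / 1000.0,
        "SHAPE_Surface_mm2": perimeter_mm * t,
        "SHAPE_Sphericity": float(sphericity),
        "SHAPE_Compacity": float(compacity),
    }


# ---------------------------------------------------------------------------
# per-subject extraction and cohort tables

def _roi_feature_vector(image: np.ndarray, mask: np.ndarray,
                        pixel_spacing: float, slice_thickness: float,
                        n_levels: int) -> dict[str, float]:
    qroi = quantize(image, mask, n_levels)
    vec = first_order_features(image, mask, qroi)
    vec.update(glcm_features(qroi))
    vec.update(glzlm_features(qroi))
    vec.update(glrlm_features(qroi))
    vec.update(shape_features(mask, pixel_spacing, slice_thickness))
    _check_invariants(qroi)
    return vec


def _check_invariants(qroi: QuantizedRoi) -> None:
    # asserted on every extraction: GLCM mass 1 and symmetric; GLZLM mass
    # balance sum(size * count) = ROI pixel count
    p = glcm_matrix(qroi)
    assert abs(p.sum() - 1.0) < 1e-9
    assert np.allclose(p, p.T, atol=1e-12)
    m = glzlm_matrix(qroi)
    sizes = np.arange(1, m.shape[1] + 1)
    assert int((m * sizes).sum()) == int(qroi.roi_mask.sum())


def extract_features(subject: Subject, slice_index: int | None = None,
                     n_levels: int = DEFAULT_GRAY_LEVELS,
                     catalog: Sequence[str] = FEATURE_CATALOG,
                     ) -> dict[str, dict[str, float]]:
    """Per-muscle feature vectors on one slice, sides averaged.

    For each muscle the full catalog is computed independently on the
    left and right ROI and the two vectors are averaged feature-wise.
    A missing side is logged and the available side used alone.
    """
    if slice_index is None:
        slice_index = subject.mid_slice_index
    if not 0 <= slice_index < len(subject.slices):
        raise IndexError(f"slice {slice_index} out of range")
    sl = subject.slices[slice_index]
    mset = subject.masks[slice_index]
    out: dict[str, dict[str, float]] = {}
    for muscle in MUSCLES:
        side_vecs = []
        for side in SIDES:
            key = f"{muscle}_{side}"
            if key not in mset.labels or not mset.labels[key].any():
                logger.warning("subject %s: missing %s side for %s; using "
                               "the available side alone",
                               subject.subject_id, side, muscle)
                continue
            side_vecs.append(_roi_feature_vector(
                sl.pixels, mset.labels[key], sl.pixel_spacing,
                sl.slice_thickness, n_levels))
        if not side_vecs:
            raise ValueError(f"subject {subject.subject_id}: no ROI for "
                             f"muscle {muscle}")
        out[muscle] = {name: float(np.mean([v[name] for v in side_vecs]))
                       for name in catalog}
    return out


def build_feature_tables(cohort: Sequence[Subject],
                         slice_selector=None,
                         n_levels: int = DEFAULT_GRAY_LEVELS,
                         ) -> dict[str, pd.DataFrame]:
    """One table per muscle: rows subjects, 56 feature columns plus the
    FF_pp and wT2_ms targets. Subjects without ground truth are skipped
    with a warning."""
    if not cohort:
        raise ValueError("empty cohort")
    rows: dict[str, list[dict]] = {m: [] for m in MUSCLES}
    for subj in cohort:
        if subj.ground_truth is None:
            logger.warning("subject %s has no ground truth; excluded",
                           subj.subject_id)
            continue
        idx = slice_selector(subj) if slice_selector else None
        feats = extract_features(subj, idx, n_levels)
        for muscle in MUSCLES:
            row = {"subject_id": subj.subject_id}
            row.update(feats[muscle])
            row["FF_pp"] = subj.ground_truth[muscle]["FF_pp"]
            row["wT2_ms"] = subj.ground_truth[muscle]["wT2_ms"]
            rows[muscle].append(row)
    if not any(rows.values()):
        raise ValueError("no subject with ground truth in cohort")
    tables = {}
    for muscle in MUSCLES:
        df = pd.DataFrame(rows[muscle])
        df = df.set_index("subject_id")
        df = df[[*FEATURE_CATALOG, "FF_pp", "wT2_ms"]]
        tables[muscle] = df
    return tables
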