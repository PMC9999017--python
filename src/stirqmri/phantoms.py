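"""Seeded synthetic calf-muscle cohorts with known ground truth.

Real STIR studies of FSHD rest on restricted patient data, so this module
generates phantom cohorts that emulate the relevant image statistics: a
healthy-control (HC) cohort whose muscles follow a single intensity law and
whose subcutaneous-fat ring carries a fat-intensity mode plus a small
"vessel" admixture, and an FSHD-like cohort whose muscle ROIs are mixtures
of suppressed-fat (low), normal-muscle (mid) and edema (high) intensity
pixels arranged as connected blobs.  Per-muscle ground-truth fat fraction
(FF, percentage points) and water T2 (wT2, ms) are tied to the latent
fat- and edema-pixel fractions by a linear-plus-Gaussian link, so that
downstream predictors have a known signal to recover.

Intensities live on an abstract 0-255-like scale; no MR physics is
simulated and masks are pre-aligned across slices.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.special import ndtr

logger = logging.getLogger(__name__)

#: The six calf muscles: Soleus, Medial/Lateral Gastrocnemius, Tibialis
#: Anterior, Extensor Digitorum Longus, Peroneus Longus.
MUSCLES = ("S", "MG", "LG", "TA", "ELD", "Pe")
SIDES = ("left", "right")
SUBCUT_FAT = "SUBCUT_FAT"

#: fixed integer encoding used in mask NIfTIs and their JSON sidecar
LABEL_IDS = {f"{m}_{s}": 1 + i * 2 + j
             for i, m in enumerate(MUSCLES) for j, s in enumerate(SIDES)}
LABEL_IDS[SUBCUT_FAT] = 13

_MUSCLE_GRID = (("S", "MG"), ("LG", "TA"), ("ELD", "Pe"))


class PhantomConfigError(ValueError):
    """Invalid phantom parameter; the message names the offending field."""


class CohortIOError(OSError):
    """Missing or corrupt cohort file; the message names the file."""


@dataclass
class PhantomParams:
    """Generator settings; intensity units are arbitrary normalized units."""

    n_subjects: int | None = None          # None -> cohort default (6 HC / 25 FSHD)
    seed: int = 0
    image_size: tuple[int, int] = (192, 192)
    pixel_spacing: float = 1.0             # mm / pixel
    slice_thickness: float = 5.0           # mm
    muscle_intensity_mean: float = 100.0
    muscle_intensity_sd: float = 10.0
    fat_intensity_mode: float = 30.0
    fat_intensity_sd: float = 8.0
    edema_intensity_mean: float = 180.0
    edema_intensity_sd: float = 15.0
    ff_noise_sd: float = 3.0               # pp
    wt2_noise_sd: float = 1.0              # ms
    ff_slope: float = 100.0                # pp per unit fat-pixel fraction
    wt2_baseline: float = 30.0             # ms
    wt2_slope: float = 25.0                # ms per unit edema-pixel fraction
    # cohort-structure knobs
    n_slices_hc: int = 6
    n_slices_fshd: int = 3
    subcut_thickness_px: int = 10          # at the reference 192-px frame size
    vessel_fraction: float = 0.04          # <=5% of subcutaneous-fat pixels
    vessel_intensity_mean: float = 220.0
    vessel_intensity_sd: float = 15.0
    f_max: float = 0.6                     # latent fat fraction ~ U(0, f_max)
    e_max: float = 0.3                     # latent edema fraction ~ U(0, e_max)
    lr_correlation: float = 0.8            # left/right latent correlation
    background_noise_sd: float = 2.0

    def validate(self) -> None:
        if self.n_subjects is not None and self.n_subjects < 2:
            raise PhantomConfigError("n_subjects must be >= 2")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise PhantomConfigError("image_size: each dimension must be >= 64")
        for name in ("muscle_intensity_sd", "fat_intensity_sd",
                     "edema_intensity_sd", "ff_noise_sd", "wt2_noise_sd"):
            if getattr(self, name) <= 0:
                raise PhantomConfigError(f"{name} must be > 0")
        if self.pixel_spacing <= 0:
            raise PhantomConfigError("pixel_spacing must be > 0")
        if self.slice_thickness <= 0:
            raise PhantomConfigError("slice_thickness must be > 0")
        if not (self.fat_intensity_mode < self.muscle_intensity_mean
                < self.edema_intensity_mean):
            raise PhantomConfigError(
                "intensity ordering violated: require fat_intensity_mode < "
                "muscle_intensity_mean < edema_intensity_mean")
        if not 0.0 <= self.vessel_fraction <= 0.05:
            raise PhantomConfigError("vessel_fraction must be in [0, 0.05]")
        if self.f_max + self.e_max > 1.0:
            raise PhantomConfigError("f_max + e_max must be <= 1")
        if not 0.0 <= self.lr_correlation <= 1.0:
            raise PhantomConfigError("lr_correlation must be in [0, 1]")


@dataclass
class SliceImage:
    """One 2D grayscale slice with its geometry."""

    pixels: np.ndarray                     # (H, W) float64, finite, >= 0
    pixel_spacing: float                   # mm
    slice_thickness: float                 # mm


@dataclass
class RoiMaskSet:
    """Integer-labelled regions: boolean mask per named ROI, disjoint."""

    labels: dict[str, np.ndarray]          # name -> (H, W) bool

    def muscles(self) -> list[str]:
        return [k for k in self.labels if k != SUBCUT_FAT]


@dataclass
class Subject:
    subject_id: str
    cohort: str                            # "HC" | "FSHD"
    slices: list[SliceImage]
    masks: list[RoiMaskSet]                # one per slice (pre-aligned)
    ground_truth: dict[str, dict[str, float]] | None = None
    latent: dict[tuple[str, str], dict[str, float]] | None = None

    @property
    def mid_slice_index(self) -> int:
        return len(self.slices) // 2


# ---------------------------------------------------------------------------
# mask layout

def build_mask_layout(image_size: tuple[int, int],
                      subcut_thickness_px: int = 10,
                      include_subcut: bool = True) -> RoiMaskSet:
    """Fixed rectangular layout: 6 muscles x 2 sides (+ optional fat ring).

    The subcutaneous ring thickness scales with image size so that every
    muscle region keeps >= 64 pixels down to 64x64 images.
    """
    h, w = image_size
    t = max(3, round(subcut_thickness_px * min(h, w) / 192))
    border = t + 4
    mid_gap = 6
    half_w = (w - 2 * border - mid_gap) // 2
    col_gap, row_gap = 4, 4
    col_w = (half_w - col_gap) // 2
    row_h = (h - 2 * border - 2 * row_gap) // 3
    labels: dict[str, np.ndarray] = {}
    if include_subcut:
        ring = np.ones(image_size, dtype=bool)
        ring[t:-t, t:-t] = False
        labels[SUBCUT_FAT] = ring
    for side in SIDES:
        x_side = border if side == "left" else w - border - half_w
        for r, row in enumerate(_MUSCLE_GRID):
            for c, muscle in enumerate(row):
                m = np.zeros(image_size, dtype=bool)
                y0 = border + r * (row_h + row_gap)
                x0 = x_side + c * (col_w + col_gap)
                m[y0:y0 + row_h, x0:x0 + col_w] = True
                labels[f"{muscle}_{side}"] = m
    for name, m in labels.items():
        if name != SUBCUT_FAT and int(m.sum()) < 64:
            raise PhantomConfigError(
                f"image_size too small: region {name} has {int(m.sum())} "
                "pixels (< 64)")
    return RoiMaskSet(labels=labels)


def _subcut_ring_mask(layout: RoiMaskSet, image_size) -> np.ndarray:
    if SUBCUT_FAT in layout.labels:
        return layout.labels[SUBCUT_FAT]
    h, w = image_size
    t = max(3, round(10 * min(h, w) / 192))
    ring = np.ones(image_size, dtype=bool)
    ring[t:-t, t:-t] = False
    return ring


# ---------------------------------------------------------------------------
# intensity laws

def _truncated_normal(rng, mean, sd, n):
    return np.clip(rng.normal(mean, sd, n), 0.0, None)


def _fill_subcut(img, ring, params, rng):
    n = int(ring.sum())
    vals = _truncated_normal(rng, params.fat_intensity_mode,
                             params.fat_intensity_sd, n)
    vessel = rng.random(n) < params.vessel_fraction
    vals[vessel] = _truncated_normal(rng, params.vessel_intensity_mean,
                                     params.vessel_intensity_sd,
                                     int(vessel.sum()))
    img[ring] = vals


def _grow_patches(avail: np.ndarray, roi: np.ndarray, n_target: int, rng,
                  patch_lo: int = 15, patch_hi: int = 120) -> np.ndarray:
    """Place ``n_target`` pixels inside ``roi & avail`` as 8-connected
    random-walk-grown patches; marks them unavailable in ``avail``.

    Connected patches keep gray-level zone statistics non-degenerate
    (pepper noise would reduce every zone to a single pixel).
    """
    out = np.zeros_like(avail)
    if n_target <= 0:
        return out
    h, w = avail.shape
    coords = np.argwhere(roi)
    order = rng.permutation(len(coords))
    seed_ptr = 0
    placed = 0
    while placed < n_target:
        while seed_ptr < len(order) and not avail[tuple(coords[order[seed_ptr]])]:
            seed_ptr += 1
        if seed_ptr >= len(order):          # ROI exhausted (cannot happen if
            break                           # fractions sum to <= 1)
        cap = min(n_target - placed, int(rng.integers(patch_lo, patch_hi + 1)))
        frontier = [tuple(coords[order[seed_ptr]])]
        patch = 0
        while frontier and patch < cap:
            k = int(rng.integers(len(frontier)))
            frontier[k], frontier[-1] = frontier[-1], frontier[k]
            y, x = frontier.pop()
            if not avail[y, x]:
                continue
            avail[y, x] = False
            out[y, x] = True
            placed += 1
            patch += 1
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and roi[ny, nx] and avail[ny, nx]:
                        frontier.append((ny, nx))
    return out


# ---------------------------------------------------------------------------
# cohort generators

def generate_hc_cohort(params: PhantomParams) -> list[Subject]:
    """Healthy-control cohort: uniform muscle law, fat ring with mode at
    ``fat_intensity_mode`` plus a small high-intensity vessel admixture."""
    params.validate()
    n_subjects = 6 if params.n_subjects is None else params.n_subjects
    rng = np.random.default_rng(params.seed)
    layout = build_mask_layout(params.image_size, params.subcut_thickness_px,
                               include_subcut=True)
    subjects = []
    for s in range(n_subjects):
        sid = f"HC{s:03d}"
        slices, masks = [], []
        for _ in range(params.n_slices_hc):
            img = np.abs(rng.normal(0.0, params.background_noise_sd,
                                    params.image_size))
            _fill_subcut(img, layout.labels[SUBCUT_FAT], params, rng)
            for name, roi in layout.labels.items():
                if name == SUBCUT_FAT:
                    continue
                img[roi] = _truncated_normal(rng, params.muscle_intensity_mean,
                                             params.muscle_intensity_sd,
                                             int(roi.sum()))
            slices.append(SliceImage(img, params.pixel_spacing,
                                     params.slice_thickness))
            masks.append(layout)
        subjects.append(Subject(sid, "HC", slices, masks))
    return subjects


def _draw_latents(params: PhantomParams, rng,
                  latent_override: tuple[float, float] | None):
    """Latent fat/edema fractions per muscle and side.

    Sides share a Gaussian-copula correlation (default 0.8): sides are
    similar, as the left/right averaging assumes, but not identical.
    Marginals are U(0, f_max) and U(0, e_max).
    """
    latent: dict[tuple[str, str], dict[str, float]] = {}
    rho = params.lr_correlation
    for muscle in MUSCLES:
        vals = {}
        for key, hi in (("f", params.f_max), ("e", params.e_max)):
            zc, z2 = rng.standard_normal(2)
            z_l = zc
            z_r = rho * zc + np.sqrt(1.0 - rho ** 2) * z2
            vals[key] = (hi * ndtr(z_l), hi * ndtr(z_r))
        for j, side in enumerate(SIDES):
            f, e = vals["f"][j], vals["e"][j]
            if latent_override is not None:
                f, e = latent_override
            latent[(muscle, side)] = {"f": float(f), "e": float(e)}
    return latent


def generate_fshd_cohort(params: PhantomParams,
                         latent_override: tuple[float, float] | None = None,
                         ) -> list[Subject]:
    """FSHD-like cohort with per-muscle ground truth.

    Per muscle-side the ROI is a mixture: a fraction ``f`` of fat-law
    pixels and ``e`` of edema-law pixels grown as connected blobs, the
    remainder muscle-law pixels.  Ground truth per muscle uses the
    left/right latent means: FF = ff_slope * f_mean + N(0, ff_noise_sd)
    clipped to [0, 100]; wT2 = wt2_baseline + wt2_slope * e_mean +
    N(0, wt2_noise_sd).
    """
    params.validate()
    n_subjects = 25 if params.n_subjects is None else params.n_subjects
    rng = np.random.default_rng(params.seed)
    layout = build_mask_layout(params.image_size, params.subcut_thickness_px,
                               include_subcut=False)
    ring = _subcut_ring_mask(layout, params.image_size)
    subjects = []
    for s in range(n_subjects):
        sid = f"FSHD{s:03d}"
        latent = _draw_latents(params, rng, latent_override)
        slices, masks = [], []
        for _ in range(params.n_slices_fshd):
            img = np.abs(rng.normal(0.0, params.background_noise_sd,
                                    params.image_size))
            _fill_subcut(img, ring, params, rng)   # unlabelled fat ring
            for muscle in MUSCLES:
                for side in SIDES:
                    roi = layout.labels[f"{muscle}_{side}"]
                    n = int(roi.sum())
                    f = latent[(muscle, side)]["f"]
                    e = latent[(muscle, side)]["e"]
                    avail = roi.copy()
                    fat = _grow_patches(avail, roi, round(f * n), rng)
                    edema = _grow_patches(avail, roi, round(e * n), rng)
                    img[roi] = _truncated_normal(
                        rng, params.muscle_intensity_mean,
                        params.muscle_intensity_sd, n)
                    img[fat] = _truncated_normal(
                        rng, params.fat_intensity_mode,
                        params.fat_intensity_sd, int(fat.sum()))
                    img[edema] = _truncated_normal(
                        rng, params.edema_intensity_mean,
                        params.edema_intensity_sd, int(edema.sum()))
            slices.append(SliceImage(img, params.pixel_spacing,
                                     params.slice_thickness))
            masks.append(layout)
        ground_truth = {}
        for muscle in MUSCLES:
            f_mean = np.mean([latent[(muscle, s_)]["f"] for s_ in SIDES])
            e_mean = np.mean([latent[(muscle, s_)]["e"] for s_ in SIDES])
            ff = params.ff_slope * f_mean + rng.normal(0.0, params.ff_noise_sd)
            wt2 = (params.wt2_baseline + params.wt2_slope * e_mean
                   + rng.normal(0.0, params.wt2_noise_sd))
            ground_truth[muscle] = {"FF_pp": float(np.clip(ff, 0.0, 100.0)),
                                    "wT2_ms": float(wt2)}
        subjects.append(Subject(sid, "FSHD", slices, masks,
                                ground_truth=ground_truth, latent=latent))
    return subjects


# ---------------------------------------------------------------------------
# serialization (NIfTI slices/masks, CSV ground truth, JSON manifest)

def write_cohort(subjects: Sequence[Subject], directory: str | Path) -> Path:
    """Serialize a cohort; returns the manifest path.

    Images and label masks go to per-subject NIfTI volumes (slices stacked
    on the third axis), the label-integer map to a JSON sidecar, ground
    truth and latent fractions to CSV, and a manifest JSON lists every
    subject-slice.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": [], "slices": []}
    gt_rows, latent_rows = [], []
    for subj in subjects:
        stack = np.stack([s.pixels for s in subj.slices], axis=-1)
        lab = np.zeros(stack.shape, dtype=np.uint16)
        for k, mset in enumerate(subj.masks):
            for name, m in mset.labels.items():
                lab[..., k][m] = LABEL_IDS[name]
        sp, th = subj.slices[0].pixel_spacing, subj.slices[0].slice_thickness
        affine = np.diag([sp, sp, th, 1.0])
        img_path = directory / f"{subj.subject_id}_image.nii.gz"
        mask_path = directory / f"{subj.subject_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(stack, affine), img_path)
        nib.save(nib.Nifti1Image(lab, affine), mask_path)
        manifest["subjects"].append({
            "subject_id": subj.subject_id, "cohort": subj.cohort,
            "n_slices": len(subj.slices),
            "pixel_spacing": sp, "slice_thickness": th,
            "labels": sorted(subj.masks[0].labels),
        })
        for k in range(len(subj.slices)):
            manifest["slices"].append({
                "subject_id": subj.subject_id, "slice_index": k,
                "image": img_path.name, "mask": mask_path.name,
            })
        if subj.ground_truth is not None:
            for muscle, gt in subj.ground_truth.items():
                gt_rows.append({"subject_id": subj.subject_id, "muscle": muscle,
                                "FF_pp": gt["FF_pp"], "wT2_ms": gt["wT2_ms"]})
        if subj.latent is not None:
            for (muscle, side), d in subj.latent.items():
                latent_rows.append({"subject_id": subj.subject_id,
                                    "muscle": muscle, "side": side,
                                    "f": d["f"], "e": d["e"]})
    with open(directory / "labels.json", "w") as fh:
        json.dump(LABEL_IDS, fh, indent=1, sort_keys=True)
    if gt_rows:
        pd.DataFrame(gt_rows).to_csv(directory / "ground_truth.csv",
                                     index=False, float_format="%.17g")
    if latent_rows:
        pd.DataFrame(latent_rows).to_csv(directory / "latent.csv",
                                         index=False, float_format="%.17g")
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path


def read_cohort(directory: str | Path) -> list[Subject]:
    """Inverse of :func:`write_cohort`; field-by-field identity."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise CohortIOError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    gt_path = directory / "ground_truth.csv"
    gt = (pd.read_csv(gt_path, float_precision="round_trip")
          if gt_path.exists() else None)
    lat_path = directory / "latent.csv"
    lat = (pd.read_csv(lat_path, float_precision="round_trip")
           if lat_path.exists() else None)
    id_to_name = {v: k for k, v in LABEL_IDS.items()}
    subjects = []
    for meta in manifest["subjects"]:
        sid = meta["subject_id"]
        img_path = directory / f"{sid}_image.nii.gz"
        mask_path = directory / f"{sid}_mask.nii.gz"
        for p in (img_path, mask_path):
            if not p.exists():
                raise CohortIOError(f"missing cohort file: {p}")
        stack = np.asarray(nib.load(img_path).get_fdata(dtype=np.float64))
        lab = np.asarray(nib.load(mask_path).dataobj)
        sp, th = meta["pixel_spacing"], meta["slice_thickness"]
        slices, masks = [], []
        for k in range(meta["n_slices"]):
            slices.append(SliceImage(stack[..., k], sp, th))
            labels = {}
            for name in meta["labels"]:
                labels[name] = lab[..., k] == LABEL_IDS[name]
            masks.append(RoiMaskSet(labels=labels))
        ground_truth = None
        if gt is not None:
            rows = gt[gt.subject_id == sid]
            if len(rows):
                ground_truth = {r.muscle: {"FF_pp": float(r.FF_pp),
                                           "wT2_ms": float(r.wT2_ms)}
                                for r in rows.itertuples()}
        latent = None
        if lat is not None:
            rows = lat[lat.subject_id == sid]
            if len(rows):
                latent = {(r.muscle, r.side): {"f": float(r.f), "e": float(r.e)}
                          for r in rows.itertuples()}
        subjects.append(Subject(sid, meta["cohort"], slices, masks,
                                ground_truth=ground_truth, latent=latent))
    return subjects
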