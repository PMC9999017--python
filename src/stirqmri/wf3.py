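"""Workflow-3 features: healthy-control reference limits and the two
bespoke per-muscle predictors FFG and MEG.

On a fat-suppressed STIR image, residual fat is dark and edema bright.
From a normalized healthy-control (HC) cohort two reference limits are
derived: a per-muscle Upper Limit UL_i = mu_i + 2 sigma_i of the pooled
healthy muscle intensity distribution, and a single Lower Limit LL equal
to the mode of the pooled subcutaneous-fat intensity histogram (the mode,
unlike the mean, is robust to the bright blood-vessel pixels inside
subcutaneous fat). For a patient muscle ROI:

* FFG (fat infiltration grade) = fraction of pixels strictly below LL;
* MEG (muscle edema grade)     = fraction of pixels strictly above UL_i.

Both are computed per side and averaged, consistent with the left/right
averaging used for the radiomic features, and serve as the single
covariates predicting FF and wT2 respectively.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phantoms import MUSCLES, SIDES, SUBCUT_FAT, Subject

logger = logging.getLogger(__name__)


@dataclass
class ReferenceLimits:
    UL: dict[str, float]               # muscle -> intensity units
    LL: float                          # intensity units
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"UL": self.UL, "LL": self.LL,
                       "provenance": self.provenance}, fh, indent=1,
                      sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceLimits":
        with open(path) as fh:
            d = json.load(fh)
        return cls(UL=d["UL"], LL=d["LL"], provenance=d.get("provenance", {}))


def _histogram_mode(values: np.ndarray, bin_width: float) -> float:
    """Mode of a 1-D sample on integer-centered bins of ``bin_width``:
    bin k covers [k*w - w/2, k*w + w/2); ties go to the lowest bin."""
    idx = np.round(np.asarray(values, dtype=np.float64) / bin_width)
    idx = idx.astype(np.int64)
    lo = idx.min()
    counts = np.bincount(idx - lo)
    return float((int(np.argmax(counts)) + lo) * bin_width)


def compute_reference_limits(hc_cohort: Sequence[Subject],
                             bin_width: float = 1.0,
                             pooling: str = "pooled") -> ReferenceLimits:
    """UL_i = mean + 2 SD (population) of pooled healthy muscle pixels;
    LL = histogram mode of pooled subcutaneous-fat pixels.

    Pixels are pooled per muscle across all HC subjects, both sides and
    all slices (``pooling="pooled"``); ``pooling="per_subject"`` instead
    computes mu + 2 sigma per subject and averages the per-subject limits.
    """
    if pooling not in ("pooled", "per_subject"):
        raise ValueError(f"unknown pooling: {pooling}")
    if not hc_cohort:
        raise ValueError("empty HC cohort")
    ul: dict[str, float] = {}
    for muscle in MUSCLES:
        per_subject = []
        pool = []
        for subj in hc_cohort:
            vals = []
            for sl, mset in zip(subj.slices, subj.masks):
                for side in SIDES:
                    key = f"{muscle}_{side}"
                    if key in mset.labels:
                        vals.append(sl.pixels[mset.labels[key]])
            if vals:
                v = np.concatenate(vals)
                per_subject.append(v.mean() + 2.0 * v.std())
                pool.append(v)
        if not pool:
            raise ValueError(f"empty muscle pixel pool for {muscle}")
        if pooling == "pooled":
            v = np.concatenate(pool)
            ul[muscle] = float(v.mean() + 2.0 * v.std())
        else:
            ul[muscle] = float(np.mean(per_subject))
    fat = []
    for subj in hc_cohort:
        for sl, mset in zip(subj.slices, subj.masks):
            if SUBCUT_FAT in mset.labels:
                fat.append(sl.pixels[mset.labels[SUBCUT_FAT]])
    if not fat:
        raise ValueError("no SUBCUT_FAT region in the HC cohort")
    ll = _histogram_mode(np.concatenate(fat), bin_width)
    if ll >= min(ul.values()):
        logger.warning("LL (%.2f) >= min UL (%.2f): reference limits look "
                       "inconsistent", ll, min(ul.values()))
    return ReferenceLimits(
        UL=ul, LL=ll,
        provenance={"hc_subjects": [s.subject_id for s in hc_cohort],
                    "bin_width": bin_width, "pooling": pooling})


@dataclass
class Wf3Features:
    FFG: float                         # fraction in [0, 1]
    MEG: float                         # fraction in [0, 1]


def compute_ffg_meg(subject: Subject, muscle: str, limits: ReferenceLimits,
                    slice_index: int | None = None) -> Wf3Features:
    """Strict-threshold pixel fractions for one muscle, sides averaged.

    FFG counts pixels with intensity < LL, MEG pixels with intensity >
    UL_muscle; the subject must be on the same intensity scale as the HC
    cohort the limits came from.
    """
    if slice_index is None:
        slice_index = subject.mid_slice_index
    sl = subject.slices[slice_index]
    mset = subject.masks[slice_index]
    ul = limits.UL[muscle]
    ffg, meg = [], []
    for side in SIDES:
        key = f"{muscle}_{side}"
        if key not in mset.labels or not mset.labels[key].any():
            continue
        vals = sl.pixels[mset.labels[key]]
        if vals.size == 0:
            raise ValueError(f"empty ROI {key}")
        ffg.append(float((vals < limits.LL).mean()))
        meg.append(float((vals > ul).mean()))
    if not ffg:
        raise ValueError(f"no ROI for muscle {muscle}")
    return Wf3Features(FFG=float(np.mean(ffg)), MEG=float(np.mean(meg)))


def build_wf3_tables(cohort: Sequence[Subject], limits: ReferenceLimits,
                     slice_index: int | None = None,
                     ) -> dict[str, dict[str, pd.DataFrame]]:
    """Per muscle, the two single-covariate datasets: (FFG, FF_pp) and
    (MEG, wT2_ms), one row per subject with ground truth."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for muscle in MUSCLES:
        ff_rows, wt2_rows = [], []
        for subj in cohort:
            if subj.ground_truth is None:
                logger.warning("subject %s has no ground truth; excluded",
                               subj.subject_id)
                continue
            w = compute_ffg_meg(subj, muscle, limits, slice_index)
            gt = subj.ground_truth[muscle]
            ff_rows.append({"subject_id": subj.subject_id, "FFG": w.FFG,
                            "FF_pp": gt["FF_pp"]})
            wt2_rows.append({"subject_id": subj.subject_id, "MEG": w.MEG,
                             "wT2_ms": gt["wT2_ms"]})
        if not ff_rows:
            raise ValueError("no subject with ground truth in cohort")
        out[muscle] = {
            "FF": pd.DataFrame(ff_rows).set_index("subject_id"),
            "wT2": pd.DataFrame(wt2_rows).set_index("subject_id"),
        }
    return out
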