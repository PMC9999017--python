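"""Inter-subject intensity harmonization via histogram matching.

Different subjects' STIR slices sit on arbitrary grayscale scales; before
any intensity feature is comparable across subjects the images are mapped
onto a common reference. The map is the monotone function sending the
image's empirical quantiles onto the reference's (exact empirical-CDF
matching, as in ``skimage.exposure.match_histograms``): it preserves
ranks within each image, lands inside the reference's [min, max], and is
exactly idempotent — renormalizing an already-normalized cohort is a
no-op, so repeated preprocessing cannot drift.

Bias-field correction is not performed here: an optional ``pre_hook``
accepts externally corrected slices, and the synthetic cohorts are
generated bias-free.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.exposure import match_histograms

from .phantoms import SliceImage, Subject

logger = logging.getLogger(__name__)


@dataclass
class HistogramMatchConfig:
    #: landmark count used when reporting quantile-agreement diagnostics;
    #: the matching map itself is the exact empirical-CDF map
    n_quantiles: int = 256
    #: subject id of the reference, or "first_hc" for the first HC subject
    #: in sorted-id order (its mid-calf slice is the reference slice)
    reference_id: str = "first_hc"

    def validate(self) -> None:
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")


def histogram_match(image: SliceImage, reference: SliceImage,
                    config: HistogramMatchConfig | None = None) -> SliceImage:
    """Map ``image`` intensities onto ``reference``'s quantile scale.

    The output is rank-preserving within the image and its range lies
    within the reference's [min, max]. Matching an image to itself is the
    identity, and the operation is idempotent.

    Raises ``ValueError`` on a constant input image (quantile map undefined).
    """
    config = config or HistogramMatchConfig()
    config.validate()
    src = np.asarray(image.pixels, dtype=np.float64)
    ref = np.asarray(reference.pixels, dtype=np.float64)
    if src.max() == src.min():
        raise ValueError("constant input image: quantile map undefined")
    if ref.max() == ref.min():
        raise ValueError("constant reference image: quantile map undefined")
    mapped = match_histograms(src, ref)
    return SliceImage(mapped, image.pixel_spacing, image.slice_thickness)


def _find_reference(subjects: Sequence[Subject],
                    config: HistogramMatchConfig) -> tuple[Subject, SliceImage]:
    if config.reference_id == "first_hc":
        hcs = sorted((s for s in subjects if s.cohort == "HC"),
                     key=lambda s: s.subject_id)
        if not hcs:
            # no HC in this cohort: fall back to first subject by id
            hcs = sorted(subjects, key=lambda s: s.subject_id)
        if not hcs:
            raise ValueError("empty cohort: no reference subject")
        ref_subj = hcs[0]
    else:
        matches = [s for s in subjects if s.subject_id == config.reference_id]
        if not matches:
            raise ValueError(f"reference subject not found: "
                             f"{config.reference_id}")
        ref_subj = matches[0]
    return ref_subj, ref_subj.slices[ref_subj.mid_slice_index]


def normalize_cohort(subjects: Sequence[Subject],
                     config: HistogramMatchConfig | None = None,
                     reference: SliceImage | None = None,
                     pre_hook: Callable[[SliceImage], SliceImage] | None = None,
                     ) -> list[Subject]:
    """Match every slice of every subject to the reference slice.

    The reference slice is the mid-calf slice of the designated reference
    subject (``config.reference_id``), or an explicit ``reference`` slice —
    passing one allows matching an FSHD cohort to an HC cohort's scale.
    The reference subject itself is returned unchanged. Subjects are
    processed independently, so cohort order does not affect the output.
    """
    config = config or HistogramMatchConfig()
    config.validate()
    ref_subj = None
    if reference is None:
        ref_subj, reference = _find_reference(subjects, config)
    out = []
    for subj in subjects:
        if ref_subj is not None and subj.subject_id == ref_subj.subject_id:
            out.append(subj)
            continue
        new_slices = []
        for sl in subj.slices:
            if pre_hook is not None:
                sl = pre_hook(sl)
            new_slices.append(histogram_match(sl, reference, config))
        out.append(Subject(subj.subject_id, subj.cohort, new_slices,
                           subj.masks, ground_truth=subj.ground_truth,
                           latent=subj.latent))
    return out
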