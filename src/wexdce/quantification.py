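"""Histology quantification and growth/percent-change arithmetic.

The percent-change convention here is fixed to the reference-relative
difference ``100 * (other - reference) / reference``; comparisons between
treated and control conditions pass the treated (or later-time) group as
the reference, which reproduces the reported treatment-effect figures
from group means (e.g. (586.7 - 472.2)/472.2 = 24.2%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = ["growth_speed", "percent_change", "positive_fraction"]


def growth_speed(records) -> np.ndarray:
    """Growth speed per counting interval: ``[Num(ct) - Num(ct-1)] / Dt``.

    Parameters
    ----------
    records:
        Table with columns ``time_h`` (strictly increasing) and ``count``;
        any count unit is accepted (cells, cells/ROI, 1e5/dish).

    Returns
    -------
    Speeds in count units per hour, length ``n - 1``.
    """
    df = pd.DataFrame(records)
    if not {"time_h", "count"}.issubset(df.columns):
        raise ValueError("records need columns (time_h, count)")
    if len(df) < 2:
        raise ValueError("need at least 2 counting time points")
    t = df["time_h"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("counting times must be strictly increasing")
    num = df["count"].to_numpy(float)
    return np.diff(num) / np.diff(t)


def percent_change(reference: float, other: float) -> float:
    """Reference-relative percent difference: ``100 (other - ref) / ref``."""
    if reference == 0:
        raise ZeroDivisionError("reference value must be non-zero")
    return 100.0 * (other - reference) / reference


def positive_fraction(
    image: np.ndarray,
    nucleus_threshold: float | None = None,
    marker_threshold: float | None = None,
) -> tuple[float, int]:
    """Fraction of segmented nuclei positive for the marker channel.

    Channel 0 is the nuclear stain, channel 1 the marker (e.g. Ki67 or
    AQP4).  Nuclei are segmented by thresholding + connected components;
    a nucleus is positive when its mean marker intensity exceeds the
    marker threshold.  Thresholds default to Otsu per channel.

    Returns
    -------
    (fraction, n_nuclei)
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 2:
        raise ValueError("expect a 2-channel image of shape (ny, nx, 2)")
    nuclei_ch, marker_ch = image[..., 0], image[..., 1]
    if nucleus_threshold is None:
        nucleus_threshold = threshold_otsu(nuclei_ch)
    if marker_threshold is None:
        # all-negative marker channels have no bimodal structure; fall back
        # to a mid-range cut so nothing spurious is counted positive
        marker_threshold = (
            threshold_otsu(marker_ch) if marker_ch.std() > 1e-6 else 0.5
        )
    labels = label(nuclei_ch > nucleus_threshold)
    props = regionprops(labels, intensity_image=marker_ch)
    if not props:
        raise ValueError("no nuclei segmented (empty field)")
    n_pos = sum(1 for p in props if p.intensity_mean > marker_threshold)
    return n_pos / len(props), len(props)
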