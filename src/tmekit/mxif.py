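"""MxIF quantification of CAF subtype abundance within tumor regions.

Each marker channel is thresholded into a binary mask; a CAF subtype mask
overlays (by default intersects) the masks of its two markers (CAF1 =
VIM & SMA, CAF2 = PDGFRa & TNC); the tumor region is the thresholded
beta-catenin mask; and abundance is the CAF-positive area inside the tumor
region normalized to the tumor area.  Group differences are assessed with
a pooled-variance two-sample Student's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu


@dataclass
class MultichannelImage:
    """(H, W, C) pixel array with named channels."""

    pixels: np.ndarray
    channel_names: Sequence[str]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (height, width, channels) array")
        if self.pixels.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must equal the channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("intensities must be finite and nonnegative")

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {list(self.channel_names)}")
        return self.pixels[:, :, idx]


@dataclass
class BinaryMask:
    """Boolean pixel mask with the provenance of how it was made."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class AbundanceRecord:
    image_id: str
    caf_label: str
    positive_area: int
    tumor_area: int

    @property
    def normalized_abundance(self) -> float:
        return self.positive_area / self.tumor_area


def threshold_channel(
    img: MultichannelImage, channel: str, threshold: float | str = "otsu"
) -> BinaryMask:
    """Binary mask of one channel: pixel is positive where intensity > threshold.

    ``threshold`` is either a fixed value or ``"otsu"`` for automatic
    bimodal-histogram selection; either way the value used is recorded in
    the mask's provenance.
    """
    values = img.channel(channel)
    if threshold == "otsu":
        if np.ptp(values) == 0:
            raise ValueError(
                f"channel {channel!r} has constant intensity; automatic thresholding "
                "is undefined — pass a fixed threshold instead"
            )
        thr = float(threshold_otsu(values))
        method = "otsu"
    else:
        thr = float(threshold)
        method = "fixed"
    return BinaryMask(
        mask=values > thr,
        provenance={"channel": channel, "threshold": thr, "method": method},
    )


def combine_masks(a: BinaryMask, b: BinaryMask, op: str = "intersection") -> BinaryMask:
    """Overlay two marker masks; co-positivity (intersection) by default."""
    if a.mask.shape != b.mask.shape:
        raise ValueError(f"mask shapes differ: {a.mask.shape} vs {b.mask.shape}")
    if op == "intersection":
        m = a.mask & b.mask
    elif op == "union":
        m = a.mask | b.mask
    else:
        raise ValueError(f"unknown op {op!r}; use 'intersection' or 'union'")
    return BinaryMask(mask=m, provenance={"op": op, "inputs": [a.provenance, b.provenance]})


def quantify_caf(
    caf_mask: BinaryMask,
    tumor_mask: BinaryMask,
    image_id: str = "",
    caf_label: str = "",
) -> AbundanceRecord:
    """CAF-positive area inside the tumor region, normalized to tumor area."""
    if caf_mask.mask.shape != tumor_mask.mask.shape:
        raise ValueError("caf_mask and tumor_mask dimensions differ")
    tumor_area = tumor_mask.area
    if tumor_area == 0:
        raise ValueError("tumor mask is empty; normalized abundance is undefined")
    positive = int((caf_mask.mask & tumor_mask.mask).sum())
    return AbundanceRecord(
        image_id=image_id, caf_label=caf_label,
        positive_area=positive, tumor_area=tumor_area,
    )


#: default marker panel: subtype -> its two marker channels
DEFAULT_PANEL: Mapping[str, tuple[str, str]] = {
    "CAF1": ("VIM", "SMA"),
    "CAF2": ("PDGFRa", "TNC"),
}


def quantify_image(
    img: MultichannelImage,
    tumor_channel: str = "bcatenin",
    panel: Mapping[str, tuple[str, str]] = DEFAULT_PANEL,
    thresholds: Mapping[str, float] | None = None,
    combine: str = "intersection",
    image_id: str = "",
) -> pd.DataFrame:
    """Full per-image quantification: one abundance row per CAF subtype.

    ``thresholds`` maps channel name -> fixed threshold; channels not
    listed use automatic Otsu selection.
    """
    thresholds = thresholds or {}

    def _mask(ch: str) -> BinaryMask:
        return threshold_channel(img, ch, thresholds.get(ch, "otsu"))

    tumor = _mask(tumor_channel)
    rows = []
    for label, (m1, m2) in panel.items():
        caf = combine_masks(_mask(m1), _mask(m2), op=combine)
        record = quantify_caf(caf, tumor, image_id=image_id, caf_label=label)
        rows.append(
            {
                "image_id": image_id,
                "caf_label": label,
                "positive_area": record.positive_area,
                "tumor_area": record.tumor_area,
                "normalized_abundance": record.normalized_abundance,
                "combine": combine,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sample pooled-variance Student's t-test.

    Returns (t, df, two-sided p) with df = n_x + n_y - 2.  Degenerate
    zero-variance inputs give p = 1 when the means agree and p = 0 (with a
    warning) when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = x.size + y.size - 2
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0", stacklevel=2)
        return float(np.inf if x.mean() > y.mean() else -np.inf), df, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), df, float(p)
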