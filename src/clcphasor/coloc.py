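"""Pearson colocalization of two-channel fluorescence images.

Computes the pixelwise Pearson correlation coefficient between two
channels, over the whole frame by default (no intensity thresholding) or
restricted to a boolean mask, and summarizes per-cell coefficients as
mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["TwoChannelImage", "pearson_coefficient", "summarize_coloc"]


@dataclass
class TwoChannelImage:
    """Two equal-shape intensity images with an optional analysis mask."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channel shapes differ")
        if np.any(self.channel_a < 0) or np.any(self.channel_b < 0):
            raise ValueError("intensities must be non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.channel_a.shape:
                raise ValueError("mask shape differs from the channels")


def pearson_coefficient(image: TwoChannelImage) -> tuple[float, int]:
    """Pearson r between the two channels over the in-mask pixels.

    Returns ``(r, n_pixels)``.  Raises if fewer than two pixels are
    available or either channel has zero variance (r undefined).
    """
    if image.mask is not None:
        a = image.channel_a[image.mask]
        b = image.channel_b[image.mask]
    else:
        a = image.channel_a.ravel()
        b = image.channel_b.ravel()
    if a.size < 2:
        raise ValueError("need at least two in-mask pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one channel: Pearson r undefined")
    r = stats.pearsonr(a, b).statistic
    return float(r), int(a.size)


def summarize_coloc(coefficients: Sequence[float]) -> tuple[float, float, int]:
    """Mean, SEM and n of per-cell Pearson coefficients."""
    r = np.asarray(coefficients, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two cells to summarize")
    return float(r.mean()), float(r.std(ddof=1) / np.sqrt(r.size)), int(r.size)
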