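"""Retina-like baseline: mean absolute per-pixel brightness difference.

The image-level difference is the mean over pixels of the absolute
luminance difference; the animation-level difference is the mean over the
9 ordered frame pairs (each of the 3 test frames against each of the 3
input frames).  The mean (rather than sum) over pixels makes the value
resolution-independent; only orderings of differences enter downstream
decisions, and those are invariant to this normalization.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .stimuli import GrayImage

__all__ = ["pixel_image_difference", "animation_difference_pixel"]


def pixel_image_difference(a: GrayImage, b: GrayImage) -> float:
    """Mean absolute luminance difference between two same-size images."""
    if (a.height, a.width) != (b.height, b.width):
        raise ValueError(
            f"images not comparable: {a.height}x{a.width} vs {b.height}x{b.width}"
        )
    return float(np.mean(np.abs(a.values - b.values)))


def animation_difference_pixel(
    test: Sequence[GrayImage], input_: Sequence[GrayImage]
) -> float:
    """Mean of the 9 pairwise image differences between two 3-frame animations."""
    if len(test) != 3 or len(input_) != 3:
        raise ValueError("animations must have exactly 3 frames")
    return float(
        np.mean([pixel_image_difference(t, i) for t in test for i in input_])
    )
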