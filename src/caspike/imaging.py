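"""ROI fluorescence quantification on grayscale image stacks.

Implements the two-projection protocol used to quantify a fluorescent fusion
in confocal z-stacks: select the 4-6 sections encompassing the structure of
interest, derive a binary mask (the ROI contour) from an automatic threshold
on the *maximal* z-projection, then measure the mean grey value under that
mask on the *average* z-projection of the same sub-stack.  Time-lapse (t, y,
x) stacks are reduced to per-nucleus fluorescence traces by averaging each
frame under an ROI mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_isodata, threshold_otsu

from .exceptions import (
    BoundsError,
    DegenerateHistogramError,
    EmptyROIError,
    InvalidParameterError,
    ShapeMismatchError,
)


@dataclass
class ImageStack:
    """A 3-D grayscale stack with a leading ``z`` (sections) or ``t`` (frames) axis."""

    data: np.ndarray
    axis: str = "z"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise InvalidParameterError("stack must be 3-D with at least one slice")
        if self.axis not in ("z", "t"):
            raise InvalidParameterError(f"leading axis must be 'z' or 't', got {self.axis!r}")
        if np.any(np.asarray(self.data, dtype=float) < 0):
            raise InvalidParameterError("stack intensities must be >= 0")

    @property
    def n_slices(self) -> int:
        return int(self.data.shape[0])

    @property
    def slice_shape(self) -> tuple[int, int]:
        return tuple(self.data.shape[1:])  # type: ignore[return-value]


@dataclass
class ROIMask:
    """A binary 2-D region of interest.

    ``provenance`` records whether the mask was derived from an automatic
    threshold or supplied externally; ``threshold`` holds the grey level used
    when threshold-derived.
    """

    mask: np.ndarray
    provenance: str = "supplied"
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InvalidParameterError("ROI mask must be 2-D")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def select_substack(stack: ImageStack, first: int, last: int) -> ImageStack:
    """Contiguous sub-stack of slices ``first..last`` (inclusive)."""
    if not (0 <= first <= last < stack.n_slices):
        raise BoundsError(
            f"slice range ({first}, {last}) out of bounds for {stack.n_slices} slices"
        )
    return ImageStack(data=stack.data[first : last + 1].copy(), axis=stack.axis)


def project(stack: ImageStack, reducer: str = "max") -> np.ndarray:
    """Collapse the stack along its leading axis by ``max`` or ``mean``."""
    if reducer == "max":
        return stack.data.max(axis=0)
    if reducer == "mean":
        return stack.data.mean(axis=0)
    raise InvalidParameterError(f"unknown reducer {reducer!r} (use 'max' or 'mean')")


def threshold_mask(image: np.ndarray, method: str = "isodata") -> ROIMask:
    """Binary foreground mask of a 2-D image.

    ``method`` is ``"isodata"`` (default, the historical ImageJ family),
    ``"otsu"``, or ``"fixed:<value>"`` for an explicit grey level.  Foreground
    is ``image >= threshold`` (bright signal on dark background).  Automatic
    methods on a uniform image raise :class:`DegenerateHistogramError`.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidParameterError("threshold_mask expects a 2-D image")
    if method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    elif method in ("isodata", "otsu"):
        if np.unique(image).size < 2:
            raise DegenerateHistogramError(
                f"automatic method {method!r} requires >= 2 distinct grey levels"
            )
        thr = float(threshold_isodata(image) if method == "isodata" else threshold_otsu(image))
    else:
        raise InvalidParameterError(f"unknown threshold method {method!r}")
    return ROIMask(mask=image >= thr, provenance="threshold-derived", threshold=thr)


def mean_gray(image: np.ndarray, mask: ROIMask) -> float:
    """Arithmetic mean of the pixels under the mask."""
    image = np.asarray(image)
    if image.shape != mask.mask.shape:
        raise ShapeMismatchError(
            f"image shape {image.shape} does not match mask shape {mask.mask.shape}"
        )
    if mask.area == 0:
        raise EmptyROIError("mean grey value requested on an empty ROI")
    return float(image[mask.mask].mean())


def quantify_roi(
    stack: ImageStack,
    first: int,
    last: int,
    method: str = "isodata",
    mask: Optional[ROIMask] = None,
) -> dict:
    """The full two-projection quantification of one sub-stack.

    Mask from the max-projection (unless supplied), mean grey value from the
    mean-projection of the same sub-stack.  Returns a dict with the threshold
    used, ROI area in pixels and the mean grey value.
    """
    sub = select_substack(stack, first, last)
    if mask is None:
        mask = threshold_mask(project(sub, "max"), method=method)
    value = mean_gray(project(sub, "mean"), mask)
    return {
        "first": first,
        "last": last,
        "method": method if mask.provenance == "threshold-derived" else "supplied-mask",
        "threshold": mask.threshold,
        "roi_area_px": mask.area,
        "mean_gray": value,
    }


def extract_trace(
    stack: ImageStack,
    mask: ROIMask,
    dt: float,
    nucleus_id: str = "roi",
    group: str = "",
    stage: str = "",
):
    """Per-frame mean intensity under a mask, as a :class:`FluorescenceTrace`.

    The stack's leading axis is interpreted as time regardless of its label.
    """
    from .traces import FluorescenceTrace  # local import to avoid a cycle

    if mask.area == 0:
        raise EmptyROIError("trace extraction requested on an empty ROI")
    if stack.slice_shape != mask.mask.shape:
        raise ShapeMismatchError(
            f"frame shape {stack.slice_shape} does not match mask shape {mask.mask.shape}"
        )
    values = stack.data[:, mask.mask].mean(axis=1)
    return FluorescenceTrace(
        nucleus_id=nucleus_id, values=values, dt=dt, group=group, stage=stage
    )
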