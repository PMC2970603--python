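"""Regions of interest and per-ROI grey-level normalization.

Each ROI is normalised independently: intensities are clipped to
[mu - 3*sigma, mu + 3*sigma] (mu, sigma = ROI mean and population standard
deviation) and linearly mapped onto Ng discrete grey levels 1..Ng.  This
windowing makes second-order texture statistics exactly invariant to positive
affine transforms of the raw intensities, which is the point of the scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

ROI_KINDS = ("WM", "NAWM", "MSi", "MSr")
ROI_LABELS = {"WM": 1, "NAWM": 2, "MSi": 3, "MSr": 4}
RECT_ROI_SHAPE = (10, 10)  # the fixed rectangular plaque ROI

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(eq=False)
class RoiMask:
    """A slice-confined pixel set, stored as sorted (row, col) coordinates."""

    rows: np.ndarray
    cols: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.intp)
        cols = np.asarray(self.cols, dtype=np.intp)
        if rows.shape != cols.shape or rows.ndim != 1:
            raise ValueError("rows and cols must be 1D arrays of equal length")
        if rows.size == 0:
            raise ValueError("ROI mask must be non-empty")
        order = np.lexsort((cols, rows))
        rows, cols = rows[order], cols[order]
        if rows.size > 1 and np.any((np.diff(rows) == 0) & (np.diff(cols) == 0)):
            raise ValueError("ROI mask contains duplicate coordinates")
        self.rows, self.cols = rows, cols

    @classmethod
    def from_rect(cls, row0: int, col0: int, height: int, width: int, kind: str) -> "RoiMask":
        """Axis-aligned rectangle, 0-based, half-open."""
        if height < 1 or width < 1:
            raise ValueError("rectangle must have positive height and width")
        rr, cc = np.mgrid[row0 : row0 + height, col0 : col0 + width]
        return cls(rows=rr.ravel(), cols=cc.ravel(), kind=kind)

    @classmethod
    def from_mask(cls, mask: np.ndarray, kind: str) -> "RoiMask":
        rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
        return cls(rows=rows, cols=cols, kind=kind)

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, col0, height, width) of the tight bounding box."""
        r0, c0 = int(self.rows.min()), int(self.cols.min())
        h = int(self.rows.max()) - r0 + 1
        w = int(self.cols.max()) - c0 + 1
        return r0, c0, h, w

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m

    def bbox_mask(self) -> np.ndarray:
        r0, c0, h, w = self.bounding_box
        m = np.zeros((h, w), dtype=bool)
        m[self.rows - r0, self.cols - c0] = True
        return m

    def is_rectangle(self, height: int, width: int) -> bool:
        r0, c0, h, w = self.bounding_box
        return h == height and w == width and self.n_pixels == height * width

    def is_four_connected(self) -> bool:
        _, n = ndimage.label(self.bbox_mask(), structure=_FOUR_CONNECTED)
        return n == 1

    def validate(self, slice_shape: tuple[int, int] | None = None) -> None:
        """Check kind-specific invariants; raise ValueError on violation."""
        if slice_shape is not None:
            bad = (self.rows < 0) | (self.rows >= slice_shape[0]) | (self.cols < 0) | (
                self.cols >= slice_shape[1]
            )
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"ROI coordinate ({int(self.rows[i])}, {int(self.cols[i])}) "
                    f"outside slice of shape {slice_shape}"
                )
        if self.kind == "MSr" and not self.is_rectangle(*RECT_ROI_SHAPE):
            raise ValueError("MSr ROI must be an axis-aligned 10x10 rectangle")
        if self.kind == "MSi" and not self.is_four_connected():
            raise ValueError("MSi ROI must be 4-connected")


@dataclass(eq=False)
class RawRoi:
    """Intensities at the masked coordinates, order-stable by (row, col)."""

    values: np.ndarray
    mask: RoiMask


@dataclass(eq=False)
class QuantizedRoi:
    """A ROI after mu +/- 3 sigma normalization.

    ``levels`` holds the quantized grey levels in 1..n_levels (used by
    co-occurrence and run-length statistics); ``clipped`` holds the clipped
    but unquantized intensities (used by histogram, gradient, wavelet and
    autoregressive statistics).  ``mu`` and ``sigma`` are the
    pre-normalization ROI mean and population standard deviation, kept at
    full precision for reporting.
    """

    levels: np.ndarray
    n_levels: int
    mu: float
    sigma: float
    clipped: np.ndarray
    mask: RoiMask
    degenerate: bool = False

    @property
    def n_pixels(self) -> int:
        return int(self.levels.size)

    def level_image(self) -> tuple[np.ndarray, np.ndarray]:
        """Quantized levels on the bounding box (0 outside the mask), plus mask."""
        r0, c0, h, w = self.mask.bounding_box
        img = np.zeros((h, w), dtype=np.int64)
        img[self.mask.rows - r0, self.mask.cols - c0] = self.levels
        return img, self.mask.bbox_mask()

    def value_image(self, fill: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Clipped intensities on the bounding box (``fill`` outside), plus mask."""
        r0, c0, h, w = self.mask.bounding_box
        img = np.full((h, w), float(fill))
        img[self.mask.rows - r0, self.mask.cols - c0] = self.clipped
        return img, self.mask.bbox_mask()


def extract_roi(slice_image, mask: RoiMask) -> RawRoi:
    """Read the slice intensities under ``mask``, ordered by (row, col)."""
    h, w = slice_image.shape
    bad = (mask.rows < 0) | (mask.rows >= h) | (mask.cols < 0) | (mask.cols >= w)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"ROI coordinate ({int(mask.rows[i])}, {int(mask.cols[i])}) outside "
            f"slice of shape {(h, w)}"
        )
    values = slice_image.pixels[mask.rows, mask.cols].astype(np.float64)
    return RawRoi(values=values, mask=mask)


def normalize_quantize(raw: RawRoi, n_levels: int = 64) -> QuantizedRoi:
    """Clip to [mu - 3 sigma, mu + 3 sigma] and quantize to 1..n_levels.

    level(x) = 1 + floor((x - (mu - 3 sigma)) / (6 sigma) * Ng), with the top
    boundary x = mu + 3 sigma assigned level Ng.  sigma is the population
    standard deviation over the ROI pixels.  A constant ROI (sigma = 0) maps
    every pixel to level ceil(Ng/2) and sets the ``degenerate`` flag so that
    feature code can apply its own degenerate-input rules.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    x = raw.values
    mu = float(x.mean())
    sigma = float(x.std())  # population (ddof=0)
    if sigma == 0.0:
        mid = math.ceil(n_levels / 2)
        return QuantizedRoi(
            levels=np.full(x.shape, mid, dtype=np.int64),
            n_levels=n_levels,
            mu=mu,
            sigma=sigma,
            clipped=x.copy(),
            mask=raw.mask,
            degenerate=True,
        )
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    clipped = np.clip(x, lo, hi)
    levels = 1 + np.floor((clipped - lo) / (6.0 * sigma) * n_levels).astype(np.int64)
    np.clip(levels, 1, n_levels, out=levels)
    return QuantizedRoi(
        levels=levels,
        n_levels=n_levels,
        mu=mu,
        sigma=sigma,
        clipped=clipped,
        mask=raw.mask,
        degenerate=False,
    )


def masks_from_labels(label_slice: np.ndarray) -> dict[str, RoiMask]:
    """Recover the four ROI kinds from an integer label image (labels 1..4)."""
    label_slice = np.asarray(label_slice)
    out: dict[str, RoiMask] = {}
    for kind, lab in ROI_LABELS.items():
        rows, cols = np.nonzero(label_slice == lab)
        if rows.size:
            out[kind] = RoiMask(rows=rows, cols=cols, kind=kind)
    return out


def read_rectangle_spec(path) -> list[RoiMask]:
    """Read rectangle ROIs from a plain-text spec.

    Each non-comment line: ``kind row col height width`` (whitespace separated,
    0-based, half-open).
    """
    masks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 'kind row col height width'")
            kind, r, c, h, w = parts[0], *map(int, parts[1:])
            masks.append(RoiMask.from_rect(r, c, h, w, kind=kind))
    return masks
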