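"""Slice containers and thick-slice simulation by intensity averaging.

A "3-mm" slice is synthesised from three consecutive thin ("1-mm") slices by
per-pixel intensity averaging followed by rounding to the nearest integer.
This mimics the partial-volume mixing of a thicker acquisition while leaving
every other imaging parameter untouched, so downstream differences can be
attributed to slice thickness alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

THIN_LABEL = "1mm"
THICK_LABEL = "3mm"
THICKNESS_LABELS = (THIN_LABEL, THICK_LABEL)


@dataclass(eq=False)
class SliceImage:
    """One 2D axial slice with its thickness label and cohort metadata."""

    pixels: np.ndarray  # 2D non-negative integer grid
    thickness_label: str
    subject: int
    level: int
    sequence: str
    slice_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice pixels must be 2D, got shape {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise TypeError(f"slice intensities must be integers, got {self.pixels.dtype}")
        if (self.pixels < 0).any():
            raise ValueError("slice intensities must be non-negative")
        if self.thickness_label not in THICKNESS_LABELS:
            raise ValueError(f"unknown thickness label {self.thickness_label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def key(self) -> tuple[int, int, str]:
        return (self.subject, self.level, self.sequence)


@dataclass(eq=False)
class VoxelVolume:
    """Stack of thin axial slices for one subject / anatomical level / sequence.

    The numeric through-plane spacing is bookkeeping only: thin slices carry
    the label ``"1mm"`` regardless of the exact spacing stored in a header
    (clinically, 0.9 mm acquisitions are treated as 1 mm).
    """

    data: np.ndarray  # (n_slices, rows, cols) non-negative integers
    subject: int
    level: int
    sequence: str
    slice_spacing_mm: float = 1.0
    pixel_spacing_mm: float = 0.45

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"volume intensities must be integers, got {self.data.dtype}")
        if (self.data < 0).any():
            raise ValueError("volume intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def middle_index(self) -> int:
        return self.n_slices // 2

    def get_slice(self, index: int, thickness_label: str = THIN_LABEL) -> SliceImage:
        if not 0 <= index < self.n_slices:
            raise IndexError(f"slice index {index} outside stack of {self.n_slices}")
        return SliceImage(
            pixels=self.data[index],
            thickness_label=thickness_label,
            subject=self.subject,
            level=self.level,
            sequence=self.sequence,
            slice_index=index,
        )

    def key(self) -> tuple[int, int, str]:
        return (self.subject, self.level, self.sequence)


def _check_compatible(a: SliceImage, b: SliceImage, name_a: str, name_b: str) -> None:
    if a.shape != b.shape:
        raise ValueError(
            f"shape mismatch between {name_a} {a.shape} and {name_b} {b.shape}"
        )
    if a.key() != b.key():
        raise ValueError(
            f"metadata mismatch between {name_a} {a.key()} and {name_b} {b.key()}"
        )


def average_stack(slices: list[SliceImage]) -> SliceImage:
    """Average an odd number of consecutive slices with half-up integer rounding.

    The accumulation is integer-exact: the k intensities are summed as
    integers and ``floor(sum/k + 1/2)`` is evaluated as ``(2*sum + k) // (2*k)``,
    so no floating-point rounding drift can occur.  Rounding of exact halves is
    half-away-from-zero (intensities are non-negative, hence half-up).
    """
    k = len(slices)
    if k < 3 or k % 2 == 0:
        raise ValueError(f"need an odd number (>= 3) of slices, got {k}")
    mid = slices[k // 2]
    names = [f"slice[{i}]" for i in range(k)]
    for s, name in zip(slices, names):
        _check_compatible(mid, s, f"slice[{k // 2}]", name)
    indices = [s.slice_index for s in slices]
    expect = list(range(mid.slice_index - k // 2, mid.slice_index + k // 2 + 1))
    if indices != expect:
        raise ValueError(
            f"slice indices {indices} are not consecutive around the middle "
            f"slice (expected {expect})"
        )
    total = np.zeros(mid.shape, dtype=np.int64)
    for s in slices:
        total += s.pixels.astype(np.int64)
    averaged = (2 * total + k) // (2 * k)  # floor(total/k + 1/2)
    return SliceImage(
        pixels=averaged,
        thickness_label=THICK_LABEL,
        subject=mid.subject,
        level=mid.level,
        sequence=mid.sequence,
        slice_index=mid.slice_index,
    )


def average_three(lower: SliceImage, middle: SliceImage, upper: SliceImage) -> SliceImage:
    """Simulate a 3-mm slice from three consecutive 1-mm slices.

    Per pixel, the three intensities are summed, divided by three and rounded
    to the nearest integer.  The output inherits the *middle* slice's metadata
    and carries the thickness label ``"3mm"``; the inputs are not modified.
    """
    _check_compatible(middle, lower, "middle", "lower")
    _check_compatible(middle, upper, "middle", "upper")
    if lower.slice_index != middle.slice_index - 1 or upper.slice_index != middle.slice_index + 1:
        raise ValueError(
            "slices are not consecutive with `middle` central: indices "
            f"({lower.slice_index}, {middle.slice_index}, {upper.slice_index})"
        )
    return average_stack([lower, middle, upper])


def simulate_thick_stack(volume: VoxelVolume, centers: list[int] | None = None) -> list[SliceImage]:
    """Simulate thick slices centred on the given thin-slice indices.

    Every centre must have both neighbours inside the stack; invalid centres
    raise (no silent skipping).  By default every interior slice is a centre.
    """
    if centers is None:
        centers = list(range(1, volume.n_slices - 1))
    centers = list(centers)
    invalid = [c for c in centers if c < 1 or c > volume.n_slices - 2]
    if invalid:
        raise ValueError(
            f"centre indices {invalid} lie at or beyond the stack boundary "
            f"(valid range 1..{volume.n_slices - 2})"
        )
    out = []
    for c in centers:
        out.append(
            average_three(
                volume.get_slice(c - 1), volume.get_slice(c), volume.get_slice(c + 1)
            )
        )
    return out
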