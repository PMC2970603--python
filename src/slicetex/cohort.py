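"""Synthetic phantom cohort emulating a multi-subject brain-MRI texture study.

No image data are deposited with the study this package rebuilds, so every
downstream stage is exercised on a phantom cohort whose *statistical*
structure mirrors the clinical material: a cohort of subjects, each imaged at
two anatomical levels with two T1-weighted sequences (plain and
contrast-enhanced), stacks of thin integer-intensity slices, and four ROI
classes per middle slice — two white-matter-like classes with nearly
identical texture (WM, NAWM) and a plaque-like class sampled under two ROI
geometries (irregular MSi, fixed 10x10 MSr) with clearly different
second-order statistics.

Texture model: a stationary Gaussian random field (white noise convolved with
an isotropic Gaussian kernel) scaled by a contrast parameter and added to a
tissue mean, optionally replaced by a causal autoregressive field; Rician
magnitude noise is added per slice, and intensities are rounded and clipped
to the integer range.  Consecutive slices share a through-plane correlation
rho so that intensity averaging changes texture realistically.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import ndimage

from .roi import ROI_LABELS, RECT_ROI_SHAPE, RoiMask
from .slices import VoxelVolume

TISSUE_CLASSES = ("WM", "NAWM", "MS")


@dataclass(frozen=True)
class TissueTextureDescriptor:
    """Second-order texture description of one tissue class.

    mean_intensity and contrast_scale are in raw intensity units;
    correlation_length is the isotropic Gaussian kernel width in pixels.
    If ``ar_coefficients`` is given (4-vector: left, upper-left, upper,
    upper-right), the field is generated by that causal autoregressive model
    instead of the Gaussian random field.
    """

    mean_intensity: float
    contrast_scale: float
    correlation_length: float
    ar_coefficients: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.contrast_scale < 0:
            raise ValueError("contrast_scale must be >= 0")
        if self.ar_coefficients is not None and len(self.ar_coefficients) != 4:
            raise ValueError("ar_coefficients must be a 4-vector")


def default_descriptors() -> dict[str, TissueTextureDescriptor]:
    """Default tissue descriptors.

    WM and NAWM share one descriptor (NAWM receives only a small zero-mean
    per-subject contrast perturbation at generation time), so they are hard
    to separate by construction.  The plaque class differs in mean (plaques
    are hypointense on T1), in contrast and — importantly for long-range
    co-occurrence statistics — in correlation length.
    """
    return {
        "WM": TissueTextureDescriptor(600.0, 30.0, 1.2),
        "NAWM": TissueTextureDescriptor(600.0, 30.0, 1.2),
        "MS": TissueTextureDescriptor(450.0, 55.0, 3.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a phantom cohort; identical spec + seed => identical cohort."""

    n_subjects: int = 23
    n_levels: int = 2
    sequences: tuple[str, ...] = ("T1", "T1C")
    slices_per_level: int = 3
    slice_shape: tuple[int, int] = (128, 128)
    intensity_depth: int = 4095
    noise_sigma: float = 4.0
    texture_params: dict[str, TissueTextureDescriptor] = field(default_factory=default_descriptors)
    seed: int = 0
    through_plane_rho: float = 0.6
    t1c_plaque_offset: float = 150.0
    enhanced_sequences: tuple[str, ...] = ("T1C",)
    nawm_perturbation: float = 0.02
    msi_size_range: tuple[int, int] = (39, 2477)
    wm_roi_shape: tuple[int, int] = (16, 16)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if not self.sequences or len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequences must be non-empty and unique")
        if self.slices_per_level < 3 or self.slices_per_level % 2 == 0:
            raise ValueError("slices_per_level must be an odd number >= 3")
        if not 0.0 <= self.through_plane_rho <= 1.0:
            raise ValueError("through_plane_rho must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.intensity_depth < 2:
            raise ValueError("intensity_depth must be >= 2")
        missing = [t for t in TISSUE_CLASSES if t not in self.texture_params]
        if missing:
            raise ValueError(f"texture_params missing tissue classes: {missing}")
        lo, hi = self.msi_size_range
        if not 1 <= lo <= hi:
            raise ValueError("msi_size_range must satisfy 1 <= lo <= hi")
        for t, d in self.texture_params.items():
            if not 0 <= d.mean_intensity <= self.intensity_depth:
                raise ValueError(f"{t} mean_intensity outside intensity depth")

    # -- JSON round trip (for config files) ---------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["texture_params"] = {
            k: dataclasses.asdict(v) for k, v in self.texture_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "texture_params" in d:
            d["texture_params"] = {
                k: TissueTextureDescriptor(**v) for k, v in d["texture_params"].items()
            }
        for key in ("sequences", "enhanced_sequences", "slice_shape", "msi_size_range",
                    "wm_roi_shape"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# texture field synthesis
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _gaussian_kernel_norm(sigma: float) -> float:
    """sqrt(sum of squared kernel weights) of scipy's truncated Gaussian filter."""
    half = int(4.0 * sigma + 0.5) + 1
    n = 2 * half + 1
    imp = np.zeros((n, n))
    imp[half, half] = 1.0
    k = ndimage.gaussian_filter(imp, sigma)
    return float(np.sqrt((k ** 2).sum()))


def _gaussian_field(rng: Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    """Unit-variance stationary Gaussian random field with kernel width corr_len."""
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, corr_len, mode="wrap")
    return f / _gaussian_kernel_norm(corr_len)


def _ar_field(rng: Generator, shape: tuple[int, int],
              theta: tuple[float, float, float, float]) -> np.ndarray:
    """Causal AR texture field, normalised to unit empirical variance.

    x(r, c) = t1*x(r, c-1) + t2*x(r-1, c-1) + t3*x(r-1, c) + t4*x(r-1, c+1) + e,
    generated with a burn-in margin so the crop is close to stationary.
    """
    t1, t2, t3, t4 = theta
    margin = 16
    h, w = shape[0] + margin, shape[1] + 2 * margin
    e = rng.standard_normal((h, w))
    x = np.zeros((h, w))
    for r in range(h):
        xr = x[r]
        xu = x[r - 1] if r > 0 else None
        for c in range(w):
            v = e[r, c]
            if c > 0:
                v += t1 * xr[c - 1]
            if xu is not None:
                if c > 0:
                    v += t2 * xu[c - 1]
                v += t3 * xu[c]
                if c + 1 < w:
                    v += t4 * xu[c + 1]
            xr[c] = v
    crop = x[margin:, margin:margin + shape[1]][: shape[0]]
    sd = crop.std()
    return crop / sd if sd > 0 else crop


def synthesize_texture(descriptor: TissueTextureDescriptor, shape: tuple[int, int],
                       rng: Generator | int) -> np.ndarray:
    """One noiseless texture field: mean + contrast * unit-variance field."""
    if not isinstance(rng, Generator):
        rng = default_rng(rng)
    if descriptor.ar_coefficients is not None:
        f = _ar_field(rng, shape, descriptor.ar_coefficients)
    else:
        f = _gaussian_field(rng, shape, descriptor.correlation_length)
    return descriptor.mean_intensity + descriptor.contrast_scale * f


def _field_stack(rng: Generator, descriptor: TissueTextureDescriptor,
                 shape: tuple[int, int], n_slices: int, rho: float) -> list[np.ndarray]:
    """Through-plane correlated stack of unit-variance fields.

    field[k+1] = rho * field[k] + sqrt(1 - rho^2) * fresh, so rho = 1 yields
    identical consecutive slices and rho = 0 independent ones.
    """

    def fresh() -> np.ndarray:
        if descriptor.ar_coefficients is not None:
            return _ar_field(rng, shape, descriptor.ar_coefficients)
        return _gaussian_field(rng, shape, descriptor.correlation_length)

    fields = [fresh()]
    mix = math.sqrt(max(0.0, 1.0 - rho * rho))
    for _ in range(n_slices - 1):
        nxt = fresh()  # drawn unconditionally to keep the stream layout fixed
        fields.append(rho * fields[-1] + mix * nxt)
    return fields


def _rician(rng: Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Rician magnitude noise: |signal + n1 + i n2| with n1, n2 ~ N(0, sigma^2)."""
    if sigma == 0.0:
        return signal
    n1 = rng.standard_normal(signal.shape) * sigma
    n2 = rng.standard_normal(signal.shape) * sigma
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def _grow_blob(rng: Generator, region: tuple[int, int, int, int], size: int) -> RoiMask:
    """Grow a 4-connected irregular blob of exactly ``size`` pixels.

    Seeded stochastic region growth (Eden model): starting from the region
    centre, a uniformly random frontier pixel is attached until the target
    count is reached.  Guarantees exact size and 4-connectivity.
    """
    r0, r1, c0, c1 = region
    if size > (r1 - r0) * (c1 - c0):
        raise ValueError(
            f"plaque mask of {size} pixels cannot fit in growth region "
            f"{(r1 - r0)}x{(c1 - c0)}"
        )
    seed = ((r0 + r1) // 2, (c0 + c1) // 2)
    chosen = {seed}
    frontier: list[tuple[int, int]] = []
    in_frontier: set[tuple[int, int]] = set()

    def push_neighbours(p: tuple[int, int]) -> None:
        r, c = p
        for q in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if r0 <= q[0] < r1 and c0 <= q[1] < c1 and q not in chosen and q not in in_frontier:
                frontier.append(q)
                in_frontier.add(q)

    push_neighbours(seed)
    while len(chosen) < size:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        p = frontier.pop()
        in_frontier.discard(p)
        chosen.add(p)
        push_neighbours(p)
    rows = np.fromiter((p[0] for p in chosen), dtype=np.intp)
    cols = np.fromiter((p[1] for p in chosen), dtype=np.intp)
    return RoiMask(rows=rows, cols=cols, kind="MSi")


@dataclass(eq=False)
class RoiLayout:
    """Per-(subject, level) ROI geometry, shared by all sequences and slices."""

    masks: dict[str, RoiMask]          # WM, NAWM, MSi, MSr
    msr_patch: tuple[int, int, int, int]  # (row0, col0, h, w) of the plaque patch


def _fixed_geometry(spec: CohortSpec) -> dict:
    """Deterministic parts of the layout, plus the blob growth region."""
    H, W = spec.slice_shape
    hh, ww = spec.wm_roi_shape
    r0, c0 = H // 10, W // 10
    patch_h = patch_w = RECT_ROI_SHAPE[0] + 4
    geo = {
        "wm": (r0, c0, hh, ww),
        "nawm": (H // 2 - hh // 2, c0, hh, ww),
        "msr_patch": (r0, W - c0 - patch_w, patch_h, patch_w),
        "blob_region": (H // 3, H - 6, W // 2, W - 6),  # (r0, r1, c0, c1)
    }
    # bounds + disjointness checks
    rects = [geo["wm"], geo["nawm"], geo["msr_patch"]]
    br = geo["blob_region"]
    occupied = np.zeros((H, W), dtype=np.int32)
    for (rr, cc, h, w) in rects:
        if rr < 0 or cc < 0 or rr + h > H or cc + w > W:
            raise ValueError(f"ROI rectangle {(rr, cc, h, w)} outside slice shape {(H, W)}")
        occupied[rr : rr + h, cc : cc + w] += 1
    if not (0 <= br[0] < br[1] <= H and 0 <= br[2] < br[3] <= W):
        raise ValueError("plaque growth region outside slice shape; enlarge slice_shape")
    occupied[br[0] : br[1], br[2] : br[3]] += 1
    if occupied.max() > 1:
        raise ValueError("ROI regions overlap; enlarge slice_shape")
    capacity = (br[1] - br[0]) * (br[3] - br[2])
    if spec.msi_size_range[1] > capacity:
        raise ValueError(
            f"largest irregular plaque ({spec.msi_size_range[1]} px) cannot fit in "
            f"the growth region ({capacity} px); enlarge slice_shape or shrink "
            "msi_size_range"
        )
    return geo


def _make_layout(spec: CohortSpec, rng: Generator, geo: dict) -> RoiLayout:
    lo, hi = spec.msi_size_range
    size = int(rng.integers(lo, hi + 1))
    blob = _grow_blob(rng, geo["blob_region"], size)
    pr, pc, ph, pw = geo["msr_patch"]
    masks = {
        "WM": RoiMask.from_rect(*geo["wm"], kind="WM"),
        "NAWM": RoiMask.from_rect(*geo["nawm"], kind="NAWM"),
        "MSi": blob,
        "MSr": RoiMask.from_rect(pr + 2, pc + 2, *RECT_ROI_SHAPE, kind="MSr"),
    }
    for kind, m in masks.items():
        m.validate(spec.slice_shape)
    return RoiLayout(masks=masks, msr_patch=geo["msr_patch"])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class CohortEntry:
    volume: VoxelVolume
    rois: dict[str, RoiMask]  # defined on the middle slice


@dataclass(eq=False)
class Cohort:
    spec: CohortSpec
    entries: list[CohortEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the phantom cohort; bit-identical for identical spec + seed."""
    geo = _fixed_geometry(spec)
    H, W = spec.slice_shape
    S = spec.slices_per_level
    dtype = np.int16 if spec.intensity_depth <= np.iinfo(np.int16).max else np.int32
    root = SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    entries: list[CohortEntry] = []
    for s_idx, s_seed in enumerate(subject_seeds):
        pert_rng = default_rng(s_seed.spawn(1)[0])
        u = float(pert_rng.uniform(-1.0, 1.0))  # per-subject NAWM perturbation
        nawm_contrast_factor = 1.0 + spec.nawm_perturbation * u
        level_seeds = s_seed.spawn(spec.n_levels)
        for l_idx, l_seed in enumerate(level_seeds):
            children = l_seed.spawn(1 + len(spec.sequences))
            layout = _make_layout(spec, default_rng(children[0]), geo)
            plaque_mask = np.zeros((H, W), dtype=bool)
            plaque_mask[layout.masks["MSi"].rows, layout.masks["MSi"].cols] = True
            pr, pc, ph, pw = layout.msr_patch
            plaque_mask[pr : pr + ph, pc : pc + pw] = True
            nm = layout.masks["NAWM"]
            nawm_mask = np.zeros((H, W), dtype=bool)
            nawm_mask[nm.rows, nm.cols] = True
            for q_idx, sequence in enumerate(spec.sequences):
                rng = default_rng(children[1 + q_idx])
                wm_d = spec.texture_params["WM"]
                nawm_d = spec.texture_params["NAWM"]
                ms_d = spec.texture_params["MS"]
                stacks = {
                    t: _field_stack(rng, d, (H, W), S, spec.through_plane_rho)
                    for t, d in (("WM", wm_d), ("NAWM", nawm_d), ("MS", ms_d))
                }
                ms_mean = ms_d.mean_intensity
                if sequence in spec.enhanced_sequences:
                    ms_mean = ms_mean + spec.t1c_plaque_offset
                data = np.empty((S, H, W), dtype=dtype)
                for k in range(S):
                    img = wm_d.mean_intensity + wm_d.contrast_scale * stacks["WM"][k]
                    img[nawm_mask] = (
                        nawm_d.mean_intensity
                        + nawm_d.contrast_scale * nawm_contrast_factor
                        * stacks["NAWM"][k][nawm_mask]
                    )
                    img[plaque_mask] = (
                        ms_mean + ms_d.contrast_scale * stacks["MS"][k][plaque_mask]
                    )
                    img = _rician(rng, img, spec.noise_sigma)
                    img = np.floor(img + 0.5)  # half-up, like the averaging step
                    np.clip(img, 0, spec.intensity_depth, out=img)
                    data[k] = img.astype(dtype)
                volume = VoxelVolume(
                    data=data, subject=s_idx, level=l_idx, sequence=sequence
                )
                entries.append(CohortEntry(volume=volume, rois=layout.masks))
    return Cohort(spec=spec, entries=entries)


# ---------------------------------------------------------------------------
# NIfTI output
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory) -> str:
    """Write the cohort as NIfTI-1 volumes plus label masks and a TSV manifest.

    Returns the manifest path.  Label volumes carry 0 background and labels
    1 WM / 2 NAWM / 3 MSi / 4 MSr on the middle slice.
    """
    import nibabel as nib

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for entry in cohort.entries:
        vol = entry.volume
        stem = f"sub{vol.subject:03d}_lev{vol.level}_{vol.sequence}"
        img_name, mask_name = f"{stem}.nii", f"{stem}_mask.nii"
        affine = np.diag(
            [vol.pixel_spacing_mm, vol.pixel_spacing_mm, vol.slice_spacing_mm, 1.0]
        )
        arr = vol.data.transpose(1, 2, 0)  # (rows, cols, slices)
        try:
            nib.save(nib.Nifti1Image(arr, affine), os.path.join(directory, img_name))
            labels = np.zeros(vol.data.shape, dtype=np.uint8)
            mid = vol.middle_index
            for kind, mask in entry.rois.items():
                labels[mid, mask.rows, mask.cols] = ROI_LABELS[kind]
            nib.save(
                nib.Nifti1Image(labels.transpose(1, 2, 0), affine),
                os.path.join(directory, mask_name),
            )
        except OSError as err:
            raise OSError(f"failed writing {os.path.join(directory, img_name)}: {err}") from err
        rows.append((vol.subject, vol.level, vol.sequence, img_name, mask_name))
    manifest = os.path.join(directory, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("subject\tlevel\tsequence\tpath\tmask_path\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    spec_path = os.path.join(directory, "cohort_spec.json")
    with open(spec_path, "w") as fh:
        json.dump(cohort.spec.to_dict(), fh, indent=2)
    return manifest


def load_cohort(manifest_path) -> list[CohortEntry]:
    """Read volumes + ROI masks back from a manifest written by write_cohort."""
    import nibabel as nib

    from .roi import masks_from_labels

    manifest_path = os.fspath(manifest_path)
    directory = os.path.dirname(manifest_path)
    entries: list[CohortEntry] = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            subject = int(parts[idx["subject"]])
            level = int(parts[idx["level"]])
            sequence = parts[idx["sequence"]]
            img = nib.load(os.path.join(directory, parts[idx["path"]]))
            data = np.asarray(img.dataobj).transpose(2, 0, 1).astype(np.int64)
            zooms = img.header.get_zooms()
            vol = VoxelVolume(
                data=data,
                subject=subject,
                level=level,
                sequence=sequence,
                slice_spacing_mm=float(zooms[2]),
                pixel_spacing_mm=float(zooms[0]),
            )
            labels = np.asarray(
                nib.load(os.path.join(directory, parts[idx["mask_path"]])).dataobj
            ).transpose(2, 0, 1)
            mid_candidates = np.flatnonzero(labels.reshape(labels.shape[0], -1).any(axis=1))
            if mid_candidates.size != 1:
                raise ValueError(
                    f"expected ROI labels on exactly one slice in {parts[idx['mask_path']]}"
                )
            rois = masks_from_labels(labels[int(mid_candidates[0])])
            entries.append(CohortEntry(volume=vol, rois=rois))
    return entries
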