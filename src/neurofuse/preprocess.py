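"""Brain-extraction preprocessing: frame averaging, blur, Otsu bounding box,
crop/resize, central-slice selection.

The chain mirrors a standard minimal pipeline for mixed MRI/PET input:

1. 4D PET stacks are collapsed to a single average image;
2. each axial slice is smoothed with a truncated, renormalized Gaussian and
   thresholded with Otsu's method;
3. the tightest 3D box containing every above-threshold voxel is cropped;
4. in-plane dimensions are resized bilinearly to a fixed size (slice count
   is never resampled);
5. the central ``n`` axial slices are kept, and intensities are min-max
   normalized per volume.

Two named configurations exist: ``paper_scale`` (13x13 blur, 128x128,
50 slices) and ``desk_scale`` (3x3 blur, 32x32, 12 slices) with the blur
kernel scaled proportionally to the in-plane size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "PreprocessConfig",
    "BoundingBox",
    "average_frames",
    "gaussian_kernel",
    "gaussian_blur",
    "otsu_threshold",
    "brain_bounding_box",
    "crop_resize",
    "central_window",
    "central_slices",
    "minmax_normalize",
    "preprocess_volume",
    "to_2d_dataset",
]


@dataclass(frozen=True)
class BoundingBox:
    """Per-axis half-open voxel intervals [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate bounding box {self.lo}..{self.hi}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


@dataclass(frozen=True)
class PreprocessConfig:
    blur_kernel: int = 13
    blur_sigma: float = 150.0
    out_hw: tuple[int, int] = (128, 128)
    n_slices: int = 50
    strict: bool = True

    @classmethod
    def paper_scale(cls) -> "PreprocessConfig":
        return cls()

    @classmethod
    def desk_scale(cls) -> "PreprocessConfig":
        # blur kernel scaled with the in-plane size (13/128 ~ 3/32)
        return cls(blur_kernel=3, blur_sigma=150.0, out_hw=(32, 32), n_slices=12)


def average_frames(v: np.ndarray) -> np.ndarray:
    """Per-voxel arithmetic mean over the time axis of a 4D PET stack."""
    v = np.asarray(v)
    if v.ndim != 4:
        raise ValueError(f"average_frames expects a 4D volume, got ndim={v.ndim}")
    # float64 accumulation so T identical frames average to the frame exactly
    return v.mean(axis=3, dtype=np.float64)


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Truncated ``size x size`` Gaussian, renormalized to sum to 1.

    At sigma >> size the kernel is near-uniform; the formula is applied as
    stated regardless.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_blur(slice2d: np.ndarray, kernel_size: int = 13,
                  sigma: float = 150.0) -> np.ndarray:
    """2D convolution with the truncated Gaussian; borders replicate edges."""
    slice2d = np.asarray(slice2d, dtype=np.float64)
    if slice2d.ndim != 2:
        raise ValueError("gaussian_blur expects a 2D slice")
    k = gaussian_kernel(kernel_size, sigma)
    return ndimage.convolve(slice2d, k, mode="nearest")


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The histogram spans the image's own min-max range with ``nbins`` bins;
    the returned value is the upper edge of the last background bin, so
    foreground is ``image > threshold``. Ties break toward the lower
    threshold.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("Otsu threshold undefined for a constant image")
    counts, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts.astype(np.float64)
    p = w / w.sum()
    omega0 = np.cumsum(p)
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    sigma_b = sigma_b[:-1]  # the last bin cannot be a split point
    # splits across empty bins are mathematically tied; take the lowest
    # threshold among all splits within float noise of the maximum
    m = sigma_b.max()
    t = int(np.flatnonzero(sigma_b >= m - 1e-10 * abs(m))[0])
    return float(edges[t + 1])


def brain_bounding_box(volume3d: np.ndarray, blur_kernel: int = 13,
                       blur_sigma: float = 150.0) -> BoundingBox:
    """Tightest 3D box containing every above-threshold voxel, where each
    axial slice is blurred then Otsu-thresholded.

    Otsu's method always splits a histogram, so a slice containing only
    background noise would contribute spurious foreground. A slice therefore
    participates only if its blurred maximum exceeds the volume-wide Otsu
    threshold of the blurred stack (i.e., it contains genuinely
    high-intensity tissue); within participating slices the stated per-slice
    threshold defines the foreground. Near-constant slices are background.
    """
    volume3d = np.asarray(volume3d, dtype=np.float64)
    if volume3d.ndim != 3:
        raise ValueError("brain_bounding_box expects a 3D volume")
    if volume3d.min() == volume3d.max():
        raise ValueError("bounding box undefined for a constant volume")
    blurred = np.stack([gaussian_blur(volume3d[:, :, d], blur_kernel, blur_sigma)
                        for d in range(volume3d.shape[2])], axis=2)
    global_t = otsu_threshold(blurred)
    mask = np.zeros(volume3d.shape, dtype=bool)
    for d in range(volume3d.shape[2]):
        b = blurred[:, :, d]
        if b.min() == b.max() or b.max() <= global_t:
            continue
        t = otsu_threshold(b)
        mask[:, :, d] = b > t
    if not mask.any():
        raise ValueError("no voxel above threshold; cannot form a bounding box")
    idx = np.argwhere(mask)
    lo = tuple(int(v) for v in idx.min(axis=0))
    hi = tuple(int(v) + 1 for v in idx.max(axis=0))
    return BoundingBox(lo=lo, hi=hi)


def crop_resize(volume3d: np.ndarray, box: BoundingBox,
                out_hw: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Crop to ``box`` and bilinearly resize each axial slice to ``out_hw``;
    the slice count is unchanged."""
    volume3d = np.asarray(volume3d, dtype=np.float64)
    crop = volume3d[box.slices()]
    target = (out_hw[0], out_hw[1], crop.shape[2])
    if crop.shape == target:
        return crop.copy()
    return _sk_resize(crop, target, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def central_window(d: int, n: int) -> tuple[int, int]:
    """Half-open slice window [start, stop) of ``n`` axial slices centered
    on floor(d/2), biasing low on odd remainders; the whole range if d < n."""
    if d < n:
        return 0, d
    start = d // 2 - n // 2 - (1 if (n % 2 == 0 and d % 2 == 1) else 0)
    start = max(0, min(start, d - n))
    return start, start + n


def central_slices(volume3d: np.ndarray, n: int = 50,
                   strict: bool = True) -> np.ndarray:
    """The ``n`` axial slices centered on floor(D/2); odd remainders bias
    low. With D < n, strict mode raises; lenient mode returns all D slices."""
    if n < 1:
        raise ValueError("n must be >= 1")
    volume3d = np.asarray(volume3d)
    d = volume3d.shape[2]
    if d < n and strict:
        raise ValueError(f"volume has {d} slices, fewer than requested {n}")
    lo, hi = central_window(d, n)
    return volume3d[:, :, lo:hi].copy()


def minmax_normalize(volume: np.ndarray) -> np.ndarray:
    """Per-volume min-max scaling to [0, 1]; constant volumes map to 0."""
    volume = np.asarray(volume, dtype=np.float64)
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        return np.zeros_like(volume)
    return (volume - lo) / (hi - lo)


def preprocess_volume(volume: np.ndarray, config: PreprocessConfig,
                      ) -> tuple[np.ndarray, dict]:
    """Full chain: (PET) frame average -> bounding box -> crop/resize ->
    central slices -> min-max normalize. Returns the model-ready volume of
    shape ``(out_hw[0], out_hw[1], n_slices)`` plus a metadata dict."""
    volume = np.asarray(volume)
    if volume.ndim == 4:
        volume = average_frames(volume)
    box = brain_bounding_box(volume, config.blur_kernel, config.blur_sigma)
    out = crop_resize(volume, box, config.out_hw)
    slice_lo, slice_hi = central_window(out.shape[2], config.n_slices)
    if out.shape[2] < config.n_slices and config.strict:
        raise ValueError(
            f"volume has {out.shape[2]} slices after cropping, fewer than "
            f"requested {config.n_slices}")
    out = out[:, :, slice_lo:slice_hi]
    out = minmax_normalize(out)
    info = {"box_lo": box.lo, "box_hi": box.hi,
            "slice_lo": slice_lo, "slice_hi": slice_hi,
            "out_shape": tuple(out.shape)}
    return out.astype(np.float32), info


def to_2d_dataset(volume3d: np.ndarray, label: int, subject_id: str = "",
                  scan_id: str = "") -> list[tuple[np.ndarray, int, dict]]:
    """Treat each axial slice as an independent 2D example inheriting the
    scan label; provenance allows regrouping to the source scan."""
    volume3d = np.asarray(volume3d)
    return [
        (volume3d[:, :, i], label,
         {"subject_id": subject_id, "scan_id": scan_id, "slice_index": i})
        for i in range(volume3d.shape[2])
    ]
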