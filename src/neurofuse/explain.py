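"""Grad-CAM relevance maps and atlas-region attribution.

For a chosen convolutional layer with feature maps ``A^k`` and the positive
class score ``yhat`` (the pre-sigmoid logit of the binary head), the neuron
importance weights are the spatially pooled gradients

    alpha_k = (1/Z) * sum_over_positions d yhat / d A^k,

with ``Z`` the number of spatial positions, and the relevance map is

    L = ReLU( sum_k alpha_k * A^k ),

which lives at the layer's (coarse) resolution and is upsampled to the input
grid by linear interpolation. Region attribution overlays the upsampled map
onto an integer atlas, averages relevance per region, and flags as critical
the regions whose mean is at or above the 90th percentile of region means.

The formulation is written with 2D pixel indices but generalizes directly to
3D: the pooling then runs over all three spatial axes and Z is the voxel
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CnnClassifier, FusionClassifier
from .nn import Conv
from .synth import ToyAtlas

__all__ = [
    "CamMap",
    "RegionAttribution",
    "gradcam",
    "fusion_gradcam",
    "upsample_cam",
    "cam_to_scan_grid",
    "region_attribution",
    "group_attribution",
]


@dataclass(frozen=True)
class CamMap:
    """Nonnegative relevance grid at the feature layer's resolution."""

    L: np.ndarray
    class_index: int
    Z: int
    alpha: np.ndarray

    def __post_init__(self):
        if (self.L < 0).any():
            raise ValueError("relevance map must be nonnegative")


@dataclass(frozen=True)
class RegionAttribution:
    """Mean relevance per atlas region, and the critical (top-percentile)
    subset."""

    means: dict[str, float]
    selected: frozenset[str]
    percentile_cut: float = 90.0
    selection_frequency: dict[str, float] | None = None


def _layer_index(net, layer):
    conv_idx = [i for i, l in enumerate(net.layers) if isinstance(l, Conv)]
    if not conv_idx:
        raise ValueError("model has no convolutional layer")
    if layer is None:
        return conv_idx[-1]
    if layer not in conv_idx:
        raise ValueError(
            f"layer {layer} is not a convolutional layer (conv layers: {conv_idx})")
    return layer


def _cam_from_net(net, x, class_index, layer):
    """Forward ``x`` (single example, batched shape) through a Sequential
    ending in a 1-unit logit; return the CAM at ``layer``'s output."""
    li = _layer_index(net, layer)
    z = net.forward(x, training=False, keep_outputs=True)
    A = net._outputs[li][0]  # (K, *spatial)
    sign = 1.0 if class_index == 1 else -1.0
    dout = np.full((1, 1), sign, dtype=np.float32)
    _, grads = net.backward(dout, collect=True)
    G = grads[li][0]  # d yhat / d A, same shape as A
    spatial_axes = tuple(range(1, A.ndim))
    Z = int(np.prod(A.shape[1:]))
    alpha = G.mean(axis=spatial_axes)
    L = np.maximum((alpha.reshape((-1,) + (1,) * (A.ndim - 1)) * A).sum(axis=0),
                   0.0)
    return CamMap(L=L.astype(np.float64), class_index=class_index, Z=Z,
                  alpha=alpha.astype(np.float64))


def gradcam(model, x, class_index: int = 1, layer: int | None = None) -> CamMap:
    """Grad-CAM for a single input on a single-branch model (or a bare
    Sequential whose output is the logit).

    ``layer`` is an index into the model's layer list and must point at a
    convolutional layer; the default is the last one.
    """
    if class_index not in (0, 1):
        raise ValueError("class_index must be 0 or 1")
    if isinstance(model, CnnClassifier):
        net = model.net
        xb = model._check(x)
    else:  # a Sequential used directly (small nets in analyses/tests)
        net = model
        xb = np.asarray(x, dtype=np.float32)
        if xb.ndim == net.layers[0].dims + 1:
            xb = xb[None]
    if xb.shape[0] != 1:
        raise ValueError("gradcam expects a single example")
    return _cam_from_net(net, xb, class_index, layer)


def fusion_gradcam(model: FusionClassifier, pair, branch: str,
                   class_index: int = 1, layer: int | None = None) -> CamMap:
    """Grad-CAM for one branch ("MRI" or "PET") of a fusion model — one map
    per modality, mirroring per-modality attribution tables."""
    if branch not in ("MRI", "PET"):
        raise ValueError("branch must be 'MRI' or 'PET'")
    xm, xp = model._check_pair(pair)
    if xm.shape[0] != 1:
        raise ValueError("fusion_gradcam expects a single scan pair")
    fm = model.branch_mri.forward(xm, training=False, keep_outputs=True)
    fp = model.branch_pet.forward(xp, training=False, keep_outputs=True)
    f = np.concatenate([fm, fp], axis=1)
    model.head.forward(f, training=False)
    sign = 1.0 if class_index == 1 else -1.0
    d = model.head.backward(np.full((1, 1), sign, dtype=np.float32))
    dm, dp = d[:, :model._split], d[:, model._split:]
    net = model.branch_mri if branch == "MRI" else model.branch_pet
    dbranch = dm if branch == "MRI" else dp
    li = _layer_index(net, layer)
    _, grads = net.backward(dbranch, collect=True)
    A = net._outputs[li][0]
    G = grads[li][0]
    spatial_axes = tuple(range(1, A.ndim))
    Z = int(np.prod(A.shape[1:]))
    alpha = G.mean(axis=spatial_axes)
    L = np.maximum((alpha.reshape((-1,) + (1,) * (A.ndim - 1)) * A).sum(axis=0),
                   0.0)
    return CamMap(L=L.astype(np.float64), class_index=class_index, Z=Z,
                  alpha=alpha.astype(np.float64))


def upsample_cam(cam: CamMap | np.ndarray,
                 target_shape: tuple[int, ...]) -> np.ndarray:
    """Linear (bi-/trilinear) interpolation of a relevance grid to the input
    resolution, with grid corners aligned; nonnegativity is preserved."""
    from scipy.ndimage import map_coordinates

    grid = cam.L if isinstance(cam, CamMap) else np.asarray(cam, dtype=np.float64)
    if len(target_shape) != grid.ndim:
        raise ValueError("target_shape must match the map's dimensionality")
    if any(t < s for t, s in zip(target_shape, grid.shape)):
        raise ValueError(
            f"target shape {target_shape} smaller than map shape {grid.shape}")
    return _linear_resize(grid, target_shape)


def _linear_resize(grid: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    """Corner-aligned linear interpolation to any shape, clipped at zero."""
    from scipy.ndimage import map_coordinates

    if tuple(target_shape) == grid.shape:
        return grid.copy()
    axes = [np.linspace(0, s - 1, t) if s > 1 else np.zeros(t)
            for s, t in zip(grid.shape, target_shape)]
    mesh = np.meshgrid(*axes, indexing="ij")
    out = map_coordinates(grid, np.stack([m.ravel() for m in mesh]),
                          order=1, mode="nearest").reshape(target_shape)
    return np.maximum(out, 0.0)


def cam_to_scan_grid(cam: CamMap | np.ndarray, info: dict,
                     scan_shape: tuple[int, int, int]) -> np.ndarray:
    """Map a CAM from the preprocessed frame back onto the original scan
    grid (and hence the atlas grid), inverting the crop/resize/slice chain.

    ``info`` is the metadata dict from :func:`preprocess_volume`. The CAM is
    upsampled to the in-plane extent of the bounding box over the retained
    slice window, then pasted into a zero volume at the box position; voxels
    the model never saw keep zero relevance.
    """
    lo, hi = info["box_lo"], info["box_hi"]
    slice_lo, slice_hi = info["slice_lo"], info["slice_hi"]
    n_kept = slice_hi - slice_lo
    target = (hi[0] - lo[0], hi[1] - lo[1], n_kept)
    grid = cam.L if isinstance(cam, CamMap) else np.asarray(cam, dtype=np.float64)
    up = _linear_resize(grid, target)
    out = np.zeros(scan_shape, dtype=np.float64)
    out[lo[0]:hi[0], lo[1]:hi[1],
        lo[2] + slice_lo:lo[2] + slice_hi] = up
    return out


def coverage_mask(info: dict, scan_shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of the voxels a preprocessed scan actually covers (its
    bounding box restricted to the retained slice window)."""
    lo, hi = info["box_lo"], info["box_hi"]
    slice_lo, slice_hi = info["slice_lo"], info["slice_hi"]
    mask = np.zeros(scan_shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2] + slice_lo:lo[2] + slice_hi] = True
    return mask


def region_attribution(relevance: np.ndarray, atlas: ToyAtlas,
                       percentile: float = 90.0,
                       mask: np.ndarray | None = None) -> RegionAttribution:
    """Mean relevance per atlas region; regions at or above the requested
    percentile of region means are selected as critical.

    With ``mask`` (e.g., the model's field of view after cropping and slice
    selection), means are taken over the region's masked voxels only, and
    regions with no masked voxel are excluded — a region the model never saw
    is not assessed rather than scored zero.
    """
    relevance = np.asarray(relevance, dtype=np.float64)
    if relevance.shape != atlas.grid_shape:
        raise ValueError(
            f"relevance shape {relevance.shape} does not match atlas grid "
            f"{atlas.grid_shape}")
    means: dict[str, float] = {}
    for r in atlas.region_ids:
        sel = atlas.labels == r
        if mask is not None:
            sel = sel & mask
        if not sel.any():
            continue
        means[atlas.names[r]] = float(relevance[sel].mean())
    values = np.array(list(means.values()))
    cut = float(np.percentile(values, percentile))
    # float-noise tolerance so exact mathematical ties (e.g., a constant
    # map) all land on the selected side
    tol = 1e-12 * max(1.0, float(np.abs(values).max()))
    selected = frozenset(name for name, m in means.items() if m >= cut - tol)
    return RegionAttribution(means=means, selected=selected,
                             percentile_cut=percentile)


def group_attribution(model, inputs, atlas: ToyAtlas,
                      layer: int | None = None, class_index: int = 1,
                      branch: str | None = None,
                      percentile: float = 90.0) -> RegionAttribution:
    """Group-level attribution for a set of scans of one class.

    Per-scan CAMs are upsampled to the atlas grid and averaged; region means
    and the percentile selection are computed on the group-mean map. The
    per-region fraction of scans in which the region was *individually*
    selected is reported alongside.
    """
    n = len(inputs)
    if n == 0:
        raise ValueError("group_attribution needs at least one scan")
    target = atlas.grid_shape
    acc = np.zeros(target, dtype=np.float64)
    counts: dict[str, int] = {atlas.names[r]: 0 for r in atlas.region_ids}
    for x in inputs:
        if branch is not None:
            cam = fusion_gradcam(model, x, branch, class_index, layer)
        else:
            cam = gradcam(model, x, class_index, layer)
        up = upsample_cam(cam, target)
        acc += up
        single = region_attribution(up, atlas, percentile)
        for name in single.selected:
            counts[name] += 1
    group_mean = acc / n
    result = region_attribution(group_mean, atlas, percentile)
    freq = {name: counts.get(name, 0) / n for name in result.means}
    return RegionAttribution(means=result.means, selected=result.selected,
                             percentile_cut=percentile,
                             selection_frequency=freq)
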