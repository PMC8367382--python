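"""Two-stage DAPI-anchored registration across imaging rounds.

Each re-hybridized round is first aligned to the round-1 DAPI by a
rigid (translation) estimate from upsampled phase cross-correlation,
then by a smooth elastic displacement field estimated with normalized
block matching on a regular grid, to absorb the nonlinear tissue
warping introduced by de-coverslipping.  All probe channels of a round
receive the transform estimated from that round's DAPI.

Displacement convention: a transform ``d`` satisfies
``moving(y, x) ~= reference(y + v(y, x), x + u(y, x))`` — i.e. it maps
moving-frame coordinates to reference-frame coordinates.  Applying the
transform resamples the moving image at ``x - d(x)``, which inverts
the warp to first order (exact for pure translations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .synthetic import RoundStack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Sub-pixel translation (dx = column, dy = row displacement, px)."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.dx, self.dy, self.theta])):
            raise ValueError("rigid transform parameters must be finite")
        if abs(self.theta) >= np.pi / 8:
            raise ValueError("|theta| must be < pi/8")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))


@dataclass(frozen=True)
class DisplacementField:
    """Dense per-pixel elastic displacement (u = col, v = row, px)."""

    u: np.ndarray
    v: np.ndarray
    sigma_field_px: float = 0.0

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def mean_magnitude(self) -> float:
        return float(np.mean(np.hypot(self.u, self.v)))

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(u=np.zeros(shape), v=np.zeros(shape))


def estimate_rigid(reference_dapi: np.ndarray, moving_dapi: np.ndarray,
                   upsample_factor: int = 20) -> RigidTransform:
    """Translation estimate from upsampled phase cross-correlation.

    Raises ``ValueError`` on constant images (no registration signal).
    """
    ref = np.asarray(reference_dapi, dtype=np.float64)
    mov = np.asarray(moving_dapi, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError("images must share a shape")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("no registration signal: constant image")
    shift, _, _ = phase_cross_correlation(ref, mov,
                                          upsample_factor=upsample_factor)
    # skimage returns (row, col) displacement under our convention
    return RigidTransform(dx=float(shift[1]), dy=float(shift[0]))


def _shift_image(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    yy, xx = np.mgrid[0: img.shape[0], 0: img.shape[1]]
    return ndi.map_coordinates(np.asarray(img, dtype=np.float64),
                               [yy - dy, xx - dx], order=1,
                               mode="constant", cval=0.0)


def estimate_elastic(
    reference_dapi: np.ndarray,
    rigidly_aligned_dapi: np.ndarray,
    grid_spacing_px: int = 64,
    search_px: int = 32,
    max_displacement_px: float = 10.0,
    upsample_factor: int = 10,
) -> DisplacementField:
    """Residual elastic field by block matching on a regular grid.

    Each ``grid_spacing_px`` block is matched to the reference by
    upsampled phase correlation; low-contrast blocks and implausibly
    large matches (> ``max_displacement_px``) are discarded and filled
    from their neighbours.  The coarse node field is interpolated with
    a bicubic upsample plus Gaussian smoothing into a dense per-pixel
    field, so the result is smooth by construction.
    """
    ref = np.asarray(reference_dapi, dtype=np.float64)
    mov = np.asarray(rigidly_aligned_dapi, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError("images must share a shape")
    h, w = ref.shape
    if grid_spacing_px > min(h, w):
        raise ValueError("grid spacing larger than image")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("no registration signal: constant image")

    ny = max(1, h // grid_spacing_px)
    nx = max(1, w // grid_spacing_px)
    node_u = np.full((ny, nx), np.nan)
    node_v = np.full((ny, nx), np.nan)
    margin = min(search_px, grid_spacing_px // 2)
    global_std = ref.std()
    for iy in range(ny):
        for ix in range(nx):
            y0 = iy * grid_spacing_px
            x0 = ix * grid_spacing_px
            y1 = min(h, y0 + grid_spacing_px + margin)
            x1 = min(w, x0 + grid_spacing_px + margin)
            y0 = max(0, y0 - margin)
            x0 = max(0, x0 - margin)
            rblk = ref[y0:y1, x0:x1]
            mblk = mov[y0:y1, x0:x1]
            if rblk.std() < 0.05 * global_std or mblk.std() < 0.05 * global_std:
                continue   # featureless block, no signal to match
            shift, err, _ = phase_cross_correlation(
                rblk, mblk, upsample_factor=upsample_factor)
            if np.hypot(*shift) > max_displacement_px:
                continue
            node_v[iy, ix] = shift[0]
            node_u[iy, ix] = shift[1]

    for arr in (node_u, node_v):
        if np.all(np.isnan(arr)):
            arr[:] = 0.0
        elif np.any(np.isnan(arr)):
            # fill rejected nodes from nearest accepted node
            mask = np.isnan(arr)
            idx = ndi.distance_transform_edt(mask, return_distances=False,
                                             return_indices=True)
            arr[:] = arr[tuple(idx)]

    def densify(nodes: np.ndarray) -> np.ndarray:
        smooth_nodes = ndi.gaussian_filter(nodes, 0.7, mode="nearest")
        d = ndi.zoom(smooth_nodes, (h / ny, w / nx), order=3, mode="nearest")
        d = d[:h, :w]
        return ndi.gaussian_filter(d, grid_spacing_px / 4.0, mode="nearest")

    u = np.clip(densify(node_u), -max_displacement_px, max_displacement_px)
    v = np.clip(densify(node_v), -max_displacement_px, max_displacement_px)
    return DisplacementField(u=u, v=v, sigma_field_px=grid_spacing_px / 4.0)


def apply_transforms(
    stack: RoundStack,
    rigid: RigidTransform | None = None,
    field: DisplacementField | None = None,
) -> RoundStack:
    """Resample all channels of a round into the reference frame.

    A single bilinear resample applies rigid + elastic jointly;
    out-of-field pixels are set to 0.  Returns a new RoundStack with
    the same dtype as the input.
    """
    rigid = rigid or RigidTransform()
    shape = stack.dapi.shape
    if field is not None and field.shape != shape:
        raise ValueError("displacement field shape mismatch")
    if rigid.dx == rigid.dy == 0.0 and (
            field is None or (not field.u.any() and not field.v.any())):
        return replace(stack, dapi=stack.dapi.copy(),
                       channels={k: im.copy()
                                 for k, im in stack.channels.items()})

    yy, xx = np.mgrid[0: shape[0], 0: shape[1]].astype(np.float64)
    cy = yy - rigid.dy - (field.v if field is not None else 0.0)
    cx = xx - rigid.dx - (field.u if field is not None else 0.0)

    def resample(img: np.ndarray) -> np.ndarray:
        if img.shape != shape:
            raise ValueError("channel shape mismatch")
        out = ndi.map_coordinates(np.asarray(img, dtype=np.float64),
                                  [cy, cx], order=1, mode="constant",
                                  cval=0.0)
        if np.issubdtype(img.dtype, np.integer):
            info = np.iinfo(img.dtype)
            out = np.clip(np.round(out), info.min, info.max)
        return out.astype(img.dtype)

    return replace(stack, dapi=resample(stack.dapi),
                   channels={k: resample(im)
                             for k, im in stack.channels.items()})


def register_round(reference_dapi: np.ndarray, stack: RoundStack,
                   grid_spacing_px: int = 64,
                   ) -> tuple[RoundStack, RigidTransform, DisplacementField]:
    """Full two-stage alignment of one round to the reference DAPI."""
    rigid = estimate_rigid(reference_dapi, stack.dapi)
    aligned_dapi = _shift_image(stack.dapi, rigid.dx, rigid.dy)
    fld = estimate_elastic(reference_dapi, aligned_dapi,
                           grid_spacing_px=grid_spacing_px)
    # compose: the elastic field was estimated in the rigidly-corrected
    # frame, which differs from the reference frame only by the (small)
    # residual, so the two stages add to first order
    registered = apply_transforms(stack, rigid, fld)
    log.info("round %d registered: rigid=(%.2f, %.2f) px, elastic mean %.2f px",
             stack.round_index, rigid.dx, rigid.dy, fld.mean_magnitude())
    return registered, rigid, fld


__all__ = [
    "RigidTransform", "DisplacementField", "estimate_rigid",
    "estimate_elastic", "apply_transforms", "register_round",
]
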