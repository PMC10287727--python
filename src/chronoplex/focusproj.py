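"""Extended-depth-of-field projection and registration for explant time-lapses.

The multi-day explant movies are z-stacks whose in-focus plane varies across
the field and drifts over days.  The pipeline per timepoint is: average the
repeated stacks → 2×2 XY binning → local-entropy focus measure per plane →
per-pixel argmax over z (focus index map) → Gaussian smoothing of the map →
interpolated projection through the original volume ("focused frame").  The
focused video is then high-pass filtered (registration only), registered
rigidly, affinely, and nonrigidly (demons) against the mean frame, cropped to
the centre 50%, rescaled between the 1st and 99th intensity percentiles, and
reduced to a mean-intensity trace.

The entropy filter is implemented from its histogram definition (per-plane
256-level quantisation; Shannon entropy in bits over a square window with
reflective padding) so that it matches a per-pixel brute-force histogram
computation to floating-point accuracy.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import correlate, gaussian_filter, map_coordinates
from scipy.optimize import minimize, minimize_scalar
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, rescale, rotate, warp

from .datatypes import ExplantTrace, FocusIndexMap, RegistrationChain, RigidTransform

# ---------------------------------------------------------------------------
# focus projection
# ---------------------------------------------------------------------------


def average_repeats(stacks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise mean of the repeated acquisitions of one timepoint."""
    stacks = [np.asarray(s, dtype=float) for s in stacks]
    if not stacks:
        raise ValueError("need at least one stack")
    shape = stacks[0].shape
    if any(s.shape != shape for s in stacks):
        raise ValueError("stacks must share a shape")
    return np.mean(stacks, axis=0)


def bin_xy(volume: np.ndarray, factor: int = 2) -> np.ndarray:
    """Block-mean binning of the trailing (Y, X) axes; leading axes untouched.

    Trailing rows/columns that do not fill a block are cropped.
    """
    volume = np.asarray(volume, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    *lead, y, x = volume.shape
    yc, xc = (y // factor) * factor, (x // factor) * factor
    v = volume[..., :yc, :xc]
    v = v.reshape(*lead, yc // factor, factor, xc // factor, factor)
    return v.mean(axis=(-3, -1))


def quantize_plane(plane: np.ndarray, levels: int = 256) -> np.ndarray:
    """Per-plane min-max quantisation to integer gray levels 0..levels-1."""
    plane = np.asarray(plane, dtype=float)
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros(plane.shape, dtype=np.int64)
    q = np.floor((plane - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def local_entropy(plane: np.ndarray, width: int = 10, levels: int = 256) -> np.ndarray:
    """Shannon entropy (bits) of the local gray-level histogram.

    The plane is quantised to ``levels`` gray values (per-plane min-max),
    then for every pixel the entropy of the histogram over the
    ``width``×``width`` neighbourhood is computed; reflective padding at the
    edges.  For even widths the window spans ``width//2 - 1`` pixels before
    and ``width//2`` after the centre in each axis.
    """
    plane = np.asarray(plane, dtype=float)
    if width > min(plane.shape):
        raise ValueError("entropy window larger than the plane")
    q = quantize_plane(plane, levels)
    present = np.unique(q)
    kernel = np.ones((width, width))
    # origin shift so an even window spans [-(w/2-1), +w/2]
    origin = 0 if width % 2 == 1 else -1
    n = float(width * width)
    ent = np.zeros(plane.shape)
    for g in present:
        counts = correlate((q == g).astype(float), kernel, mode="reflect", origin=(origin, origin))
        p = counts / n
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    return ent


def entropy_volume(stack: np.ndarray, width: int = 10, levels: int = 256) -> np.ndarray:
    """Per-plane local entropy of a (Z, Y, X) stack."""
    return np.stack([local_entropy(p, width=width, levels=levels) for p in stack])


def entropy_argmax(entropy: np.ndarray) -> FocusIndexMap:
    """Per-pixel z index of maximum entropy (ties broken toward low z)."""
    entropy = np.asarray(entropy, dtype=float)
    raw = np.argmax(entropy, axis=0)
    return FocusIndexMap(index=raw.astype(float), raw_index=raw)


def smooth_index_map(fmap: FocusIndexMap, width: float = 20.0, z_max: Optional[float] = None) -> FocusIndexMap:
    """Gaussian-smooth the focus index map (sigma = width / 2, reflective edges)."""
    idx = gaussian_filter(fmap.index.astype(float), sigma=width / 2.0, mode="reflect")
    if z_max is not None:
        idx = np.clip(idx, 0.0, z_max)
    return FocusIndexMap(index=idx, raw_index=fmap.raw_index)


def apply_index_map(stack: np.ndarray, fmap: FocusIndexMap) -> np.ndarray:
    """Project the stack through the (fractional) focus index map.

    Per pixel, intensity is linearly interpolated between the planes
    bracketing the index.
    """
    stack = np.asarray(stack, dtype=float)
    z_n = stack.shape[0]
    idx = np.clip(fmap.index, 0.0, z_n - 1)
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, z_n - 1)
    frac = idx - lo
    iy, ix = np.meshgrid(np.arange(stack.shape[1]), np.arange(stack.shape[2]), indexing="ij")
    return (1.0 - frac) * stack[lo, iy, ix] + frac * stack[hi, iy, ix]


def focus_project_stack(stack: np.ndarray, entropy_width: int = 10, smooth_width: float = 20.0) -> Tuple[np.ndarray, FocusIndexMap]:
    """Entropy → argmax → smooth → apply, for a single (Z, Y, X) stack."""
    ent = entropy_volume(stack, width=entropy_width)
    fmap = entropy_argmax(ent)
    fmap = smooth_index_map(fmap, width=smooth_width, z_max=stack.shape[0] - 1)
    return apply_index_map(stack, fmap), fmap


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def high_pass(frames: np.ndarray, background_sigma: float = 50.0) -> np.ndarray:
    """Subtract the Gaussian-blurred background from each frame.

    Used only to drive registration; intensity quantification always runs on
    unfiltered frames.
    """
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    out = np.stack([f - gaussian_filter(f, sigma=background_sigma, mode="reflect") for f in frames])
    return out[0] if single else out


def _apply_rigid(frame: np.ndarray, tr: RigidTransform) -> np.ndarray:
    rot = rotate(frame, tr.theta_deg, order=1, mode="symmetric", preserve_range=True)
    tform = AffineTransform(translation=(tr.dx, tr.dy))
    return warp(rot, tform.inverse, order=1, mode="symmetric", preserve_range=True)


def register_rigid(frames: np.ndarray, reference: np.ndarray, max_angle_deg: float = 5.0,
                   upsample: int = 20) -> Tuple[List[RigidTransform], np.ndarray]:
    """Rigid (translation + rotation) registration of each frame to a reference.

    Translation by subpixel phase correlation; rotation by a bounded
    golden-section search on the phase-correlation error after rotating the
    frame about its centre.  Degenerate (constant) frames get identity.
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    transforms: List[RigidTransform] = []
    aligned = np.empty_like(frames)
    for i, frame in enumerate(frames):
        if frame.std() == 0 or reference.std() == 0:
            transforms.append(RigidTransform(0.0, 0.0, 0.0))
            aligned[i] = frame
            continue

        def neg_quality(theta: float, _frame=frame) -> float:
            rot = rotate(_frame, theta, order=1, mode="symmetric", preserve_range=True)
            _, error, _ = phase_cross_correlation(reference, rot, upsample_factor=upsample, normalization=None)
            return float(error)

        res = minimize_scalar(neg_quality, bounds=(-max_angle_deg, max_angle_deg), method="bounded",
                              options={"xatol": 0.01})
        theta = float(res.x) if res.fun < neg_quality(0.0) else 0.0
        rot = rotate(frame, theta, order=1, mode="symmetric", preserve_range=True)
        shift, _, _ = phase_cross_correlation(reference, rot, upsample_factor=upsample, normalization=None)
        tr = RigidTransform(dy=float(shift[0]), dx=float(shift[1]), theta_deg=theta)
        transforms.append(tr)
        aligned[i] = _apply_rigid(frame, tr)
    return transforms, aligned


def _affine_params_to_matrix(p: np.ndarray) -> np.ndarray:
    m = np.eye(3)
    m[0, 0], m[0, 1], m[0, 2] = p[0], p[1], p[2]
    m[1, 0], m[1, 1], m[1, 2] = p[3], p[4], p[5]
    return m


def _warp_affine(frame: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    # matrix maps output (x, y, 1) -> input coordinates (skimage convention)
    return warp(frame, AffineTransform(matrix=matrix), order=1, mode="symmetric", preserve_range=True)


def register_affine(frames: np.ndarray, reference: np.ndarray) -> Tuple[List[np.ndarray], np.ndarray]:
    """6-parameter affine registration by derivative-free MSE minimisation.

    Frames should be rigidly pre-aligned; the optimiser starts from the
    identity, and a frame whose optimised MSE exceeds its identity MSE keeps
    the identity (fallback to the rigid result).
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    matrices: List[np.ndarray] = []
    aligned = np.empty_like(frames)
    cy, cx = (np.array(reference.shape) - 1) / 2.0

    def center_matrix(p: np.ndarray) -> np.ndarray:
        # parametrize the linear part about the image centre so translation and
        # scale are decoupled
        m = _affine_params_to_matrix(p)
        t_to = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
        t_from = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
        return t_to @ m @ t_from

    for i, frame in enumerate(frames):
        def cost(p: np.ndarray, _frame=frame) -> float:
            moved = _warp_affine(_frame, center_matrix(p))
            return float(np.mean((moved - reference) ** 2))

        p0 = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        mse0 = cost(p0)
        res = minimize(cost, p0, method="Powell",
                       options={"xtol": 1e-6, "ftol": 1e-10, "maxfev": 4000})
        if np.isfinite(res.fun) and res.fun <= mse0:
            m = center_matrix(res.x)
        else:
            m = np.eye(3)
        matrices.append(m)
        aligned[i] = _warp_affine(frame, m)
    return matrices, aligned


def _warp_with_field(frame: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Resample ``frame`` at ``x + u(x)`` (pull-back warp by displacement field)."""
    yy, xx = np.meshgrid(np.arange(frame.shape[0]), np.arange(frame.shape[1]), indexing="ij")
    return map_coordinates(frame, [yy + field[0], xx + field[1]], order=1, mode="reflect")


def _demons_single_level(fixed: np.ndarray, moving: np.ndarray, field: np.ndarray,
                         sigma_reg: float, n_iter: int) -> np.ndarray:
    gy, gx = np.gradient(fixed)
    grad_sq = gy**2 + gx**2
    for _ in range(n_iter):
        warped = _warp_with_field(moving, field)
        # intensity-difference-driven update; sign matches the pull-back
        # convention warped(x) = moving(x + u(x))
        diff = fixed - warped
        denom = grad_sq + diff**2
        with np.errstate(divide="ignore", invalid="ignore"):
            uy = np.where(denom > 1e-12, diff * gy / denom, 0.0)
            ux = np.where(denom > 1e-12, diff * gx / denom, 0.0)
        update = np.stack([uy, ux])
        if not np.all(np.isfinite(update)):
            raise FloatingPointError("non-finite demons update")
        field = field + update
        field = np.stack([gaussian_filter(field[0], sigma_reg, mode="reflect"),
                          gaussian_filter(field[1], sigma_reg, mode="reflect")])
    return field


def register_demons(frames: np.ndarray, reference: Optional[np.ndarray] = None,
                    sigma_reg: float = 2.0, n_iter: int = 60, n_levels: int = 3) -> Tuple[List[np.ndarray], np.ndarray]:
    """Nonrigid demons registration of each frame to the mean-frame reference.

    Classic intensity demons: per-iteration update
    ``u = (m - f) * grad(f) / (|grad(f)|^2 + (m - f)^2)`` accumulated into a
    dense displacement field that is Gaussian-regularised (``sigma_reg``)
    after every iteration, run coarse-to-fine over an ``n_levels`` pyramid.
    A frame whose update turns non-finite falls back to a zero field.
    """
    frames = np.asarray(frames, dtype=float)
    if reference is None:
        reference = frames.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    fields: List[np.ndarray] = []
    aligned = np.empty_like(frames)
    for i, frame in enumerate(frames):
        field = None
        try:
            for level in range(n_levels - 1, -1, -1):
                factor = 2 ** level
                f_small = rescale(reference, 1.0 / factor, order=1, mode="reflect",
                                  anti_aliasing=factor > 1, preserve_range=True)
                m_small = rescale(frame, 1.0 / factor, order=1, mode="reflect",
                                  anti_aliasing=factor > 1, preserve_range=True)
                if field is None:
                    field = np.zeros((2,) + f_small.shape)
                else:
                    field = np.stack([
                        _resize_field(field[0], f_small.shape) * 2.0,
                        _resize_field(field[1], f_small.shape) * 2.0,
                    ])
                field = _demons_single_level(f_small, m_small, field, sigma_reg, n_iter)
            if field.shape[1:] != frame.shape:
                field = np.stack([_resize_field(field[0], frame.shape), _resize_field(field[1], frame.shape)])
        except FloatingPointError:
            field = np.zeros((2,) + frame.shape)
        fields.append(field)
        aligned[i] = _warp_with_field(frame, field)
    return fields, aligned


def _resize_field(component: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    zy = shape[0] / component.shape[0]
    zx = shape[1] / component.shape[1]
    yy, xx = np.meshgrid(np.arange(shape[0]) / zy, np.arange(shape[1]) / zx, indexing="ij")
    return map_coordinates(component, [yy, xx], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# final normalisation and trace extraction
# ---------------------------------------------------------------------------


def crop_center(frames: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Crop every frame to the central ``fraction`` of each spatial axis."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    frames = np.asarray(frames)
    y, x = frames.shape[-2:]
    ny, nx = int(y * fraction), int(x * fraction)
    y0, x0 = (y - ny) // 2, (x - nx) // 2
    return frames[..., y0:y0 + ny, x0:x0 + nx]


def rescale_percentiles(frames: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0,
                        per_frame: bool = False) -> np.ndarray:
    """Rescale intensities so the p_lo/p_hi percentiles map to 0/1, clipping outside.

    Percentiles are computed jointly over the whole movie by default (keeping
    the fluorescence change across frames comparable between trials); set
    ``per_frame=True`` to normalise each frame independently.
    """
    if p_lo >= p_hi:
        raise ValueError("p_lo must be < p_hi")
    frames = np.asarray(frames, dtype=float)
    if per_frame and frames.ndim == 3:
        return np.stack([rescale_percentiles(f, p_lo, p_hi) for f in frames])
    lo, hi = np.percentile(frames, [p_lo, p_hi])
    if hi == lo:
        raise ValueError("degenerate intensity distribution: percentiles coincide")
    return np.clip((frames - lo) / (hi - lo), 0.0, 1.0)


def mean_intensity_trace(frames: np.ndarray, frame_interval_min: float = 30.0) -> ExplantTrace:
    """Spatial mean of each (rescaled) frame against recording time."""
    frames = np.asarray(frames, dtype=float)
    means = frames.reshape(frames.shape[0], -1).mean(axis=1)
    time_h = np.arange(frames.shape[0]) * frame_interval_min / 60.0
    return ExplantTrace(time_h=time_h, mean_norm_intensity=means)


def run_focus_pipeline(
    movie_data: np.ndarray,
    frame_interval_min: float = 30.0,
    bin_factor: int = 2,
    entropy_width: int = 10,
    smooth_width: float = 20.0,
    background_sigma: float = 50.0,
    crop_fraction: float = 0.5,
    percentiles: Tuple[float, float] = (1.0, 99.0),
    do_rigid: bool = True,
    do_affine: bool = True,
    do_demons: bool = True,
    demons_kwargs: Optional[dict] = None,
) -> Tuple[ExplantTrace, np.ndarray, RegistrationChain, List[FocusIndexMap]]:
    """Full pipeline from a (T, Z, Y, X) volume to the normalised intensity trace.

    Registration transforms are estimated on high-passed focused frames and
    applied to the unfiltered focused frames.
    """
    movie_data = np.asarray(movie_data, dtype=float)
    binned = bin_xy(movie_data, bin_factor) if bin_factor > 1 else movie_data

    focused = []
    maps: List[FocusIndexMap] = []
    for t in range(binned.shape[0]):
        frame, fmap = focus_project_stack(binned[t], entropy_width=entropy_width, smooth_width=smooth_width)
        focused.append(frame)
        maps.append(fmap)
    focused = np.stack(focused)

    chain = RegistrationChain()
    registered = focused
    hp = high_pass(registered, background_sigma=background_sigma)
    if do_rigid and registered.shape[0] >= 2:
        ref = hp.mean(axis=0)
        chain.rigid, hp = register_rigid(hp, ref)
        registered = np.stack([_apply_rigid(f, tr) for f, tr in zip(registered, chain.rigid)])
    if do_affine and registered.shape[0] >= 2:
        ref = hp.mean(axis=0)
        chain.affine, hp = register_affine(hp, ref)
        registered = np.stack([_warp_affine(f, m) for f, m in zip(registered, chain.affine)])
    if do_demons and registered.shape[0] >= 2:
        ref = hp.mean(axis=0)
        chain.displacement, _ = register_demons(hp, ref, **(demons_kwargs or {}))
        registered = np.stack([_warp_with_field(f, u) for f, u in zip(registered, chain.displacement)])

    cropped = crop_center(registered, crop_fraction)
    rescaled = rescale_percentiles(cropped, *percentiles)
    trace = mean_intensity_trace(rescaled, frame_interval_min)
    return trace, rescaled, chain, maps
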