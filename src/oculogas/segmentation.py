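"""Gas-volume measurement: Otsu thresholding, per-slice masks, integration.

The measurement mirrors an image-analysis workflow on T2-like slices: an
automatic Otsu threshold separates bright intraocular fluid from everything
dark (gas, sclera, background); the globe is located as the largest bright
connected component; the vitreous-cavity disk is recovered by a robust
circle fit to the fluid boundary (the gas-fluid meniscus chord is rejected
as outliers); gas is the dark area inside that disk.  Per-slice areas are
integrated across the stack and the gas volume is reported as a percentage
of the vitreous cavity.

The Otsu threshold is computed on a histogram restricted to a bounding box
around the eye, because background air would otherwise dominate the class
statistics.  Ties in the between-class variance are broken toward the
lowest threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label, regionprops

from .phantom import ImageStack

__all__ = [
    "otsu_threshold",
    "otsu_threshold_image",
    "fit_circle_trimmed",
    "segment_slice",
    "segment_stack",
    "gas_volume_percent",
    "SliceSegmentation",
    "SegmentationResult",
]


def otsu_threshold(hist: np.ndarray, bin_values: np.ndarray | None = None) -> float:
    """Otsu's threshold from an intensity histogram.

    Returns the bin value ``t`` maximizing the between-class variance
    ``sigma_B^2(t) = w0 w1 (mu0 - mu1)^2`` of the split into a dark class
    ``{value <= t}`` and a bright class ``{value > t}``.  Among ties the
    lowest ``t`` is returned.  Raises if fewer than two bins are occupied.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be a 1-D array with at least two bins")
    if bin_values is None:
        bin_values = np.arange(hist.size, dtype=float)
    else:
        bin_values = np.asarray(bin_values, dtype=float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("histogram has fewer than two occupied bins: no separable classes")

    w0 = np.cumsum(hist)
    total = w0[-1]
    m0 = np.cumsum(hist * bin_values)
    mtot = m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros_like(w0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        sigma_b[valid] = w0[valid] * w1[valid] * (mu0[valid] - mu1[valid]) ** 2
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(bin_values[best])


def eye_roi(image: np.ndarray, margin_px: int = 10) -> tuple[slice, slice]:
    """Bounding box around the eye (pixels above mid-range, grown by a margin).

    Falls back to the whole image when nothing is bright.
    """
    image = np.asarray(image)
    lo, hi = float(image.min()), float(image.max())
    rough = image > (lo + hi) / 2.0
    if not rough.any():
        return slice(0, image.shape[0]), slice(0, image.shape[1])
    rows = np.flatnonzero(rough.any(axis=1))
    cols = np.flatnonzero(rough.any(axis=0))
    return (
        slice(max(rows[0] - margin_px, 0), min(rows[-1] + margin_px + 1, image.shape[0])),
        slice(max(cols[0] - margin_px, 0), min(cols[-1] + margin_px + 1, image.shape[1])),
    )


def otsu_threshold_image(image: np.ndarray, margin_px: int = 10) -> float:
    """Otsu threshold of a slice, restricted to a box around the eye.

    Background air would otherwise dominate the class statistics.
    """
    image = np.asarray(image)
    if float(image.min()) == float(image.max()):
        raise ValueError("constant image: no separable classes")
    roi = image[eye_roi(image, margin_px)]
    hist = np.bincount(roi.astype(np.uint8).ravel(), minlength=256)
    return otsu_threshold(hist)


def fit_circle_trimmed(points_xy: np.ndarray, trim: float, n_iter: int = 4):
    """Least-squares circle fit with iterative outlier trimming.

    Algebraic (Kasa) fit, refit ``n_iter`` times keeping only points within
    ``trim`` of the current circle.  Used to recover the cavity circle from
    a fluid boundary that includes the straight meniscus chord: chord points
    are far from the circle and get trimmed away.
    """
    pts = np.asarray(points_xy, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 boundary points for a circle fit")

    def kasa(p):
        A = np.column_stack([p[:, 0], p[:, 1], np.ones(len(p))])
        b = (p ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        cx, cy = sol[0] / 2.0, sol[1] / 2.0
        r = np.sqrt(max(sol[2] + cx * cx + cy * cy, 0.0))
        return cx, cy, r

    cx, cy, r = kasa(pts)
    for _ in range(n_iter):
        res = np.abs(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r)
        keep = res < trim
        if keep.sum() < 3 or keep.all():
            break
        cx, cy, r = kasa(pts[keep])
    return cx, cy, r


def _refine_circle(image: np.ndarray, cx: float, cy: float, r: float, dx: float,
                   n_rays: int = 720, n_iter: int = 2):
    """Sub-pixel refinement of the cavity circle by radial edge localization.

    Along rays from the circle center, the wall is located at the extremum
    of the radial intensity gradient (with a parabolic sub-sample fit): for
    a blurred edge the gradient peak sits on the edge, and unlike a level
    crossing it is not biased by the thin scleral rim, whose far side
    bleeds into any fixed-level rule.  The per-ray sampling phase relative
    to the pixel grid varies around the circle, so residual per-ray
    quantization averages out in the circle fit.  Rays with too little
    inside/outside contrast (e.g. through the meniscus corner) are skipped,
    and a trimmed fit drops residual outliers.
    """
    from scipy.ndimage import map_coordinates

    ang = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
    ca, sa = np.cos(ang), np.sin(ang)
    step = 0.25 * dx
    img = image.astype(np.float32)
    for _ in range(n_iter):
        ts = np.arange(r - 3.0 * dx, r + 2.0 * dx + 1e-9, step)
        px = cx + ts[None, :] * ca[:, None]
        py = cy + ts[None, :] * sa[:, None]
        prof = map_coordinates(
            img, [py.ravel() / dx, px.ravel() / dx], order=1, mode="nearest"
        ).reshape(n_rays, ts.size)
        n_in = int(round(1.5 * dx / step))         # [r-3dx, r-1.5dx]
        i_out0 = np.searchsorted(ts, r + 0.5 * dx)
        inside = prof[:, :n_in].mean(axis=1)
        outer = prof[:, i_out0:].mean(axis=1)
        contrast = inside - outer
        deriv = np.gradient(prof, axis=1)
        window = (ts > r - 1.5 * dx) & (ts < r + 1.5 * dx)
        idx = np.nonzero(window)[0]
        pts, bright_inside = [], []
        for i in range(n_rays):
            if abs(contrast[i]) < 25:
                continue
            d = -deriv[i] * np.sign(contrast[i])  # positive at the inner wall edge
            j = idx[np.argmax(d[idx])]
            if j <= 0 or j >= ts.size - 1:
                continue
            denom = d[j - 1] - 2.0 * d[j] + d[j + 1]
            off = 0.5 * (d[j - 1] - d[j + 1]) / denom if denom != 0 else 0.0
            off = float(np.clip(off, -1.0, 1.0))
            t_edge = ts[j] + off * step
            pts.append((cx + t_edge * ca[i], cy + t_edge * sa[i]))
            bright_inside.append(contrast[i] > 0)
        if len(pts) < n_rays // 4:
            return cx, cy, r  # keep the coarse fit
        pts = np.asarray(pts)
        bright_inside = np.asarray(bright_inside)
        # Rays looking out from bright fluid localize the wall cleanly (a
        # falling fluid/sclera edge); from inside the gas the rim is a
        # narrow low bump whose gradient peak sits slightly inside the
        # wall.  Anchor the radius on the fluid rays, then absorb the
        # gas-side bias into a shared radial offset so that both arcs
        # still constrain the center (a single-arc fit leaves the center
        # poorly determined along the gas/fluid axis).
        n_fluid = int(bright_inside.sum())
        n_gas = len(pts) - n_fluid
        min_arc = max(n_rays // 6, 60)
        if n_fluid >= min_arc and n_gas >= min_arc:
            cx, cy, r = fit_circle_trimmed(pts[bright_inside], trim=1.5 * dx, n_iter=2)
            for _ in range(2):
                gas_pts = pts[~bright_inside]
                dist_gas = np.hypot(gas_pts[:, 0] - cx, gas_pts[:, 1] - cy)
                delta = float(np.median(dist_gas - r))
                radial = (gas_pts - [cx, cy]) / dist_gas[:, None]
                corrected = np.vstack([pts[bright_inside], gas_pts - delta * radial])
                cx, cy, r = fit_circle_trimmed(corrected, trim=1.5 * dx, n_iter=2)
        elif n_fluid >= min_arc:
            cx, cy, r = fit_circle_trimmed(pts[bright_inside], trim=1.5 * dx, n_iter=2)
        else:
            cx, cy, r = fit_circle_trimmed(pts, trim=1.5 * dx, n_iter=2)
    return cx, cy, r


@dataclass
class SliceSegmentation:
    """Masks, areas and the fitted cavity circle for one slice."""

    threshold: float
    cavity_mask: np.ndarray
    gas_mask: np.ndarray
    fluid_mask: np.ndarray
    cavity_area_mm2: float
    gas_area_mm2: float
    circle_xy_mm: tuple  # fitted cavity-circle center, image mm
    circle_r_mm: float
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.gas_area_mm2 > self.cavity_area_mm2 + 1e-9:
            raise ValueError("gas area exceeds cavity area")


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) of mask pixels with at least one non-mask 4-neighbour."""
    interior = mask.copy()
    interior[1:, :] &= mask[:-1, :]
    interior[:-1, :] &= mask[1:, :]
    interior[:, 1:] &= mask[:, :-1]
    interior[:, :-1] &= mask[:, 1:]
    return np.column_stack(np.nonzero(mask & ~interior))


def _largest_component(mask: np.ndarray):
    lbl = label(mask)
    if lbl.max() == 0:
        return None
    largest = max(regionprops(lbl), key=lambda p: p.area)
    return lbl == largest.label, largest.area


def segment_slice(
    image: np.ndarray,
    threshold: float,
    pixel_spacing_mm: float,
    min_gas_area_mm2: float = 2.0,
) -> SliceSegmentation:
    """Segment the vitreous cavity and intraocular gas on one slice.

    Bright class = intraocular fluid (largest bright connected component,
    holes filled).  Because both the gas bubble and the scleral wall are
    dark, the cavity boundary is recovered from the eye wall itself: a
    second Otsu split among the sub-threshold pixels isolates the
    mid-intensity scleral rim, whose enclosed interior is the cavity disk;
    a trimmed circle fit to that interior's boundary gives the cavity
    circle.  Gas = dark components inside the circle above a small area
    floor (sub-pixel edge slivers are dropped); cavity = fluid inside the
    circle union gas.  Areas are pixel counts times the squared pixel
    spacing.  This also handles a fully gas-filled cavity, where no bright
    fluid exists at all.
    """
    image = np.asarray(image)
    dx = pixel_spacing_mm

    def _empty(flag: str) -> SliceSegmentation:
        z = np.zeros(image.shape, bool)
        return SliceSegmentation(
            threshold=threshold,
            cavity_mask=z,
            gas_mask=z.copy(),
            fluid_mask=z.copy(),
            cavity_area_mm2=0.0,
            gas_area_mm2=0.0,
            circle_xy_mm=(np.nan, np.nan),
            circle_r_mm=np.nan,
            flags=[flag],
        )

    bright = image > threshold
    rim = None
    no_fluid = False
    found_bright = _largest_component(bright)
    if found_bright is not None and found_bright[1] >= 20:
        filled = binary_fill_holes(found_bright[0])
        if filled.sum() > 1.5 * found_bright[1]:
            # The largest bright component is annular: with no fluid at all
            # (fully gas-filled cavity) the threshold lands between air and
            # the scleral rim, and the rim itself is the bright ring.
            rim = found_bright[0]
            no_fluid = True

    if rim is None:
        # Scleral rim: sub-threshold pixels elevated above the gas and
        # background level.  The dark class is a large spike at the air/gas
        # intensity plus the rim and blur-transition tail, so a robust
        # location/scale rule (median + 4 MAD, floored at 8 intensity
        # units) separates "elevated" from "background" at any noise level.
        roi = image[eye_roi(image)]
        dark_vals = roi[roi <= threshold].astype(float)
        if dark_vals.size == 0:
            return _empty("no_dark_class")
        med = float(np.median(dark_vals))
        mad = 1.4826 * float(np.median(np.abs(dark_vals - med)))
        t_rim = med + max(4.0 * mad, 8.0)
        if t_rim >= threshold:
            return _empty("no_rim_class")
        rim_cand = (image > t_rim) & ~bright
        found = _largest_component(rim_cand)
        if found is None or found[1] < 20:
            return _empty("no_rim")
        rim = found[0]
    globe = binary_fill_holes(rim)
    enclosed = globe & ~rim
    if enclosed.sum() < 20:
        return _empty("no_cavity_interior")

    # The enclosed interior is the cavity disk, possibly split by the
    # blurred gas-fluid meniscus line (which also falls in the rim's
    # intensity class).  Fit the cavity circle to interior-boundary points
    # near the wall only, so the meniscus chord cannot contaminate the fit.
    rc = _boundary_points(enclosed)
    pts = np.column_stack([rc[:, 1] * dx, rc[:, 0] * dx])  # mm: x = col*dx, y = row*dx
    rr_g, cc_g = np.nonzero(globe)
    cx, cy = float(cc_g.mean()) * dx, float(rr_g.mean()) * dx
    r_globe = math.sqrt(globe.sum() * dx * dx / math.pi)
    d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    near_wall = d > r_globe - 2.5
    if near_wall.sum() < 20:
        return _empty("no_wall_support")
    r = float(np.median(d[near_wall]))
    for _ in range(3):
        gate = np.abs(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r) < 3.0 * dx
        if gate.sum() < 10:
            return _empty("circle_fit_failed")
        cx, cy, r = fit_circle_trimmed(pts[gate], trim=2.0 * dx, n_iter=1)
    # Validate: the circle must be well supported around its circumference
    # and must actually enclose the interior region.
    d_fin = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    inliers = np.abs(d_fin - r) < 2.0 * dx
    ang = np.arctan2(pts[inliers, 1] - cy, pts[inliers, 0] - cx)
    bins = np.unique((ang // (2 * math.pi / 36)).astype(int))
    if len(bins) < 24 or enclosed.sum() * dx * dx < 0.5 * math.pi * r * r:
        return _empty("circle_fit_failed")
    cx, cy, r = _refine_circle(image, cx, cy, r, dx)

    # Classify every pixel of the cavity disk by the fluid threshold.  Gas
    # and fluid share the same geometric boundary (the fitted circle), so a
    # small radius error perturbs both areas proportionally and largely
    # cancels in the gas/cavity ratio.
    rows = np.arange(image.shape[0])[:, None] * dx
    cols = np.arange(image.shape[1])[None, :] * dx
    dist = np.hypot(cols - cx, rows - cy)
    flags = []
    disk = dist <= r
    if no_fluid:
        flags.append("no_fluid_class")
        fluid = np.zeros_like(disk)
        gas_cand = disk
    else:
        fluid = bright & disk
        gas_cand = (~bright) & disk
    gas = np.zeros_like(gas_cand)
    lbl_g = label(gas_cand)
    min_px = max(int(round(min_gas_area_mm2 / dx**2)), 1)
    kept = 0
    for p in regionprops(lbl_g):
        if p.area >= min_px:
            gas |= lbl_g == p.label
            kept += 1
    if kept > 1:
        flags.append("multi_component_gas")
        warnings.warn("multiple dark components inside the cavity; all kept", stacklevel=2)
    cavity = fluid | gas

    # Gas area with partial-volume weighting in the disk interior: the
    # blurred intensity of a pixel is its coverage-weighted mix of the gas
    # and fluid plateaus, so fractional weights on meniscus-transition
    # pixels remove the whole-row quantization a binary count suffers when
    # the flat interface falls near a pixel-row boundary.  The annulus
    # within 1.5 px of the wall is counted binarily (scleral bleed would
    # corrupt the fractions), as is everything outside the transition band.
    gas_area = float(gas.sum()) * dx**2
    if not no_fluid and gas.any():
        vals = image[disk].astype(float)
        i_gas, i_fluid = np.percentile(vals, [5, 95])
        if i_fluid - i_gas > 40:
            interior = dist <= r - 1.5 * dx
            frac = np.clip((i_fluid - image.astype(float)) / (i_fluid - i_gas), 0.0, 1.0)
            band = interior & (frac > 0.1) & (frac < 0.9)
            solid = interior & (frac >= 0.9) & gas
            gas_area = (
                float(frac[band].sum())
                + float(solid.sum())
                + float((gas & ~interior).sum())
            ) * dx**2
            gas_area = min(gas_area, float(cavity.sum()) * dx**2)
    return SliceSegmentation(
        threshold=threshold,
        cavity_mask=cavity,
        gas_mask=gas,
        fluid_mask=fluid,
        cavity_area_mm2=float(cavity.sum()) * dx**2,
        gas_area_mm2=gas_area,
        circle_xy_mm=(cx, cy),
        circle_r_mm=r,
        flags=flags,
    )


@dataclass
class SegmentationResult:
    """Per-slice segmentations plus the stack-level gas volume percentage."""

    slices: list
    pixel_spacing_mm: float
    slice_spacings_mm: np.ndarray

    @property
    def gas_volume_pct(self) -> float:
        return gas_volume_percent(self.slices, self.slice_spacings_mm)

    def per_slice_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "slice_idx": i,
                    "threshold": s.threshold,
                    "cavity_mm2": s.cavity_area_mm2,
                    "gas_mm2": s.gas_area_mm2,
                    "flags": ";".join(s.flags),
                }
                for i, s in enumerate(self.slices)
            ]
        )


def segment_stack(stack: ImageStack, min_gas_area_mm2: float = 2.0) -> SegmentationResult:
    """Segment every slice of a stack with a per-slice Otsu threshold.

    Slices without a usable bright component (e.g. fully dark lateral
    slices) are flagged and contribute nothing to either area sum.
    """
    out = []
    for k in range(stack.n_slices):
        img = stack.data[k]
        try:
            t = otsu_threshold_image(img)
        except ValueError:
            out.append(
                SliceSegmentation(
                    threshold=np.nan,
                    cavity_mask=np.zeros(img.shape, bool),
                    gas_mask=np.zeros(img.shape, bool),
                    fluid_mask=np.zeros(img.shape, bool),
                    cavity_area_mm2=0.0,
                    gas_area_mm2=0.0,
                    circle_xy_mm=(np.nan, np.nan),
                    circle_r_mm=np.nan,
                    flags=["constant_slice"],
                )
            )
            continue
        out.append(segment_slice(img, t, stack.pixel_spacing_mm, min_gas_area_mm2))
    spacings = np.full(stack.n_slices, stack.slice_spacing_mm)
    return SegmentationResult(out, stack.pixel_spacing_mm, spacings)


def gas_volume_percent(slices, slice_spacings_mm) -> float:
    """Gas volume as a percentage of the vitreous cavity.

    Ratio of spacing-weighted area sums, ``100 * sum(gas_k w_k) /
    sum(cavity_k w_k)``; for uniform spacing this equals the volumetric
    ratio of the two integrated volumes.  Raises when no cavity area was
    found at all.
    """
    w = np.asarray(slice_spacings_mm, dtype=float)
    gas = np.array([s.gas_area_mm2 for s in slices])
    cav = np.array([s.cavity_area_mm2 for s in slices])
    if len(w) != len(gas):
        raise ValueError("spacings and slice results differ in length")
    denom = float((cav * w).sum())
    if denom <= 0:
        raise ValueError("zero total cavity area: nothing segmented")
    return 100.0 * float((gas * w).sum()) / denom
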