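"""Slice-level ocular measurements: landmarks, retinal parts, contact, angle.

Operates on a segmented sagittal slice in image millimetres (``x = col *
pixel_spacing`` increasing toward head-superior, ``y = row * pixel_spacing``
increasing downward, so the anti-gravity direction is ``(0, -1)``).

The measurement chain mirrors the manual procedure on a single slice:

1. choose the slice whose anterior-posterior extent matches the eye's
   axial length;
2. drop a line perpendicular to the pupillary axis from each anterior
   chamber angle; its intersection with the ocular surface is the surgical
   limbus;
3. walk 7 mm and 13.5 mm of arc posterior to the limbus along the contour
   to place the ora serrata and the equator;
4. split the retina into superior/inferior x anterior/posterior parts
   (posterior = pupillary-axis intersection to equator, anterior = equator
   to ora serrata) and measure, per part, the length in contact with gas;
5. measure the supraduction angle between the pupillary axis and the
   gravity-perpendicular line, signed positive toward head-superior, with
   the reference direction flipping between supine and prone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import PART_NAMES, ContactRateResult, EQUATOR_MM, ORA_SERRATA_MM

__all__ = [
    "SliceGeometry",
    "SupraductionAngle",
    "PartitionedContour",
    "circle_contour",
    "select_slice",
    "locate_limbus",
    "place_landmarks",
    "partition_retina",
    "measure_contact",
    "locate_meniscus",
    "measure_contact_plane",
    "measure_supraduction",
    "axis_from_angle_points",
]


# ---------------------------------------------------------------------------
# Closed-polyline utilities.  Contours are (N, 2) arrays of vertices in mm;
# the closing edge from the last back to the first vertex is implicit.

def _edges(contour: np.ndarray) -> np.ndarray:
    return np.roll(contour, -1, axis=0) - contour


def contour_length(contour: np.ndarray) -> float:
    return float(np.linalg.norm(_edges(contour), axis=1).sum())


def _cumlen(contour: np.ndarray) -> np.ndarray:
    """Arc-length of each vertex; element N equals the full perimeter."""
    seg = np.linalg.norm(_edges(contour), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at(contour: np.ndarray, s: float) -> np.ndarray:
    """Point at arc position ``s`` (wrapped) along the closed contour."""
    cum = _cumlen(contour)
    L = cum[-1]
    s = s % L
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(contour) - 1)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (s - cum[i]) / seg
    nxt = contour[(i + 1) % len(contour)]
    return contour[i] + t * (nxt - contour[i])


def project_point(contour: np.ndarray, p) -> float:
    """Arc position of the closest contour point to ``p``."""
    p = np.asarray(p, dtype=float)
    a = contour
    e = _edges(contour)
    ee = (e * e).sum(axis=1)
    t = np.clip(((p - a) * e).sum(axis=1) / np.where(ee == 0, 1.0, ee), 0.0, 1.0)
    proj = a + t[:, None] * e
    d2 = ((proj - p) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    cum = _cumlen(contour)
    return float(cum[i] + t[i] * math.sqrt(ee[i]))


def extract_arc(contour: np.ndarray, s0: float, s1: float, direction: int) -> np.ndarray:
    """Sub-polyline from arc position ``s0`` to ``s1`` walking in ``direction``.

    ``direction`` +1 walks toward increasing arc position (vertex order),
    -1 the other way.  Endpoints are included as exact interpolated points.
    """
    cum = _cumlen(contour)
    L = cum[-1]
    s0m, s1m = s0 % L, s1 % L
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    span = (s1m - s0m) % L if direction == 1 else (s0m - s1m) % L
    # Interior vertices strictly between s0 and s1 along the walk.
    pts = [point_at(contour, s0m)]
    n = len(contour)
    if direction == 1:
        start = np.searchsorted(cum, s0m, side="right")
        k = 0
        while k < n:
            s_v = cum[(start + k) % n] if (start + k) < n else cum[(start + k) % n] + L
            off = (s_v - s0m) % L
            if off >= span or off == 0:
                break
            pts.append(contour[(start + k) % n])
            k += 1
    else:
        start = np.searchsorted(cum[:n], s0m, side="left") - 1
        k = 0
        while k < n:
            idx = (start - k) % n
            off = (s0m - cum[idx]) % L
            if off >= span or off == 0:
                break
            pts.append(contour[idx])
            k += 1
    pts.append(point_at(contour, s1m))
    return np.asarray(pts)


def arc_span(contour: np.ndarray, s0: float, s1: float, direction: int) -> float:
    L = _cumlen(contour)[-1]
    return ((s1 - s0) % L) if direction == 1 else ((s0 - s1) % L)


def line_intersections(contour: np.ndarray, p0, d) -> list[np.ndarray]:
    """All intersections of the infinite line ``p0 + t d`` with the contour."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(d, dtype=float)
    a = contour
    e = _edges(contour)
    # Solve p0 + t d = a_i + u e_i with u in [0, 1).
    denom = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])
    rhs = a - p0
    out = []
    for i in range(len(a)):
        det = -d[0] * e[i, 1] + d[1] * e[i, 0]
        if abs(det) < 1e-12:
            continue
        t = (rhs[i, 0] * (-e[i, 1]) + rhs[i, 1] * e[i, 0]) / det
        u = (d[0] * rhs[i, 1] - d[1] * rhs[i, 0]) / det
        if 0.0 <= u < 1.0:
            out.append(a[i] + u * e[i])
    return out


def circle_contour(center_xy, radius: float, n: int = 2048) -> np.ndarray:
    """Dense polygonal contour of a circle (used for fitted cavity circles)."""
    th = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([center_xy[0] + radius * np.cos(th),
                            center_xy[1] + radius * np.sin(th)])


# ---------------------------------------------------------------------------


@dataclass
class SliceGeometry:
    """Everything needed to measure one segmented slice.

    ``contour`` is the ocular (retinal) contour in image mm; the pupillary
    axis passes through ``axis_point`` along the unit vector ``axis_dir``
    (pointing anterior); ``superior_dir`` is the eye's head-superior unit
    vector in the image plane.  Angle landmarks come from the phantom
    sidecar (or a schematic detector).
    """

    contour: np.ndarray
    axis_point: np.ndarray
    axis_dir: np.ndarray
    superior_dir: np.ndarray
    angle_superior: np.ndarray
    angle_inferior: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self):
        self.contour = np.asarray(self.contour, dtype=float)
        for name in ("axis_point", "axis_dir", "superior_dir", "angle_superior", "angle_inferior"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = np.linalg.norm(self.axis_dir)
        if n == 0:
            raise ValueError("pupillary axis direction undefined")
        self.axis_dir = self.axis_dir / n
        self.superior_dir = self.superior_dir / np.linalg.norm(self.superior_dir)


@dataclass
class SupraductionAngle:
    """Signed eye rotation (deg) against the gravity-perpendicular line."""

    degrees: float
    posture: str

    def __post_init__(self):
        if not abs(self.degrees) < 90:
            raise ValueError("supraduction angle must satisfy |angle| < 90 deg")


def select_slice(seg_result, axial_length_mm: float,
                 anterior_offset_mm: float = 1.6, max_error_mm: float = 2.0) -> int:
    """Index of the slice whose axial extent best matches the axial length.

    The anterior-posterior extent of each slice is the fitted cavity
    diameter plus the corneal/anterior-chamber offset; the slice minimizing
    the absolute mismatch wins, ties going to the lower index.
    """
    best_idx, best_err = None, np.inf
    for i, s in enumerate(seg_result.slices):
        if not np.isfinite(s.circle_r_mm):
            continue
        extent = 2.0 * s.circle_r_mm + anterior_offset_mm
        err = abs(extent - axial_length_mm)
        if err < best_err - 1e-12:
            best_idx, best_err = i, err
    if best_idx is None or best_err > max_error_mm:
        raise ValueError(
            f"no slice within {max_error_mm} mm of the axial length {axial_length_mm} mm"
        )
    return best_idx


def _side_of(geom: SliceGeometry, p) -> float:
    return float((np.asarray(p) - geom.axis_point) @ geom.superior_dir)


def locate_limbus(geom: SliceGeometry) -> dict:
    """Surgical limbus per side: perpendicular from the angle to the surface.

    For each anterior-chamber angle point, the line perpendicular to the
    pupillary axis through that point is intersected with the contour; the
    intersection on the same (superior/inferior) side, closest to the angle
    point, is the limbus.
    """
    perp = np.array([-geom.axis_dir[1], geom.axis_dir[0]])
    out = {}
    for name, angle_pt in (("superior", geom.angle_superior), ("inferior", geom.angle_inferior)):
        side = 1.0 if name == "superior" else -1.0
        hits = line_intersections(geom.contour, angle_pt, perp)
        same = [p for p in hits if side * _side_of(geom, p) > 0]
        if not same:
            raise ValueError(f"no {name} limbus: perpendicular from the angle misses the contour")
        d = [np.linalg.norm(p - angle_pt) for p in same]
        out[name] = same[int(np.argmin(d))]
    return out


def _posterior_direction(geom: SliceGeometry, s: float) -> int:
    """Walk direction (+1/-1) that moves posteriorly (decreasing axial coord)."""
    eps = 0.25 * geom.pixel_spacing_mm

    def u(pt):
        return float((pt - geom.axis_point) @ geom.axis_dir)

    u_fwd = u(point_at(geom.contour, s + eps))
    u_bwd = u(point_at(geom.contour, s - eps))
    return 1 if u_fwd < u_bwd else -1


def place_landmarks(geom: SliceGeometry, limbus: dict | None = None,
                    ora_mm: float = ORA_SERRATA_MM, equator_mm: float = EQUATOR_MM) -> dict:
    """Ora serrata and equator per side, at fixed arc distances from the limbus.

    Distances are walked posteriorly along the contour (arc length, not
    chord).  Returns a dict of named points plus their arc positions and
    the posterior walk direction per side.
    """
    if limbus is None:
        limbus = locate_limbus(geom)
    L = contour_length(geom.contour)
    if equator_mm >= L / 2:
        raise ValueError("contour too short for the landmark distances")
    out = {"limbus": limbus, "s": {}, "direction": {}}
    for side in ("superior", "inferior"):
        s_l = project_point(geom.contour, limbus[side])
        d = _posterior_direction(geom, s_l)
        out["direction"][side] = d
        out["s"][f"limbus_{side}"] = s_l
        out["s"][f"ora_{side}"] = (s_l + d * ora_mm) % L
        out["s"][f"equator_{side}"] = (s_l + d * equator_mm) % L
        out[f"ora_{side}"] = point_at(geom.contour, out["s"][f"ora_{side}"])
        out[f"equator_{side}"] = point_at(geom.contour, out["s"][f"equator_{side}"])
    return out


@dataclass
class PartitionedContour:
    """Four retinal parts as sub-polylines of a measured contour."""

    parts: dict  # name -> (M, 2) polyline
    lengths_mm: dict
    landmarks: dict
    pole_xy: np.ndarray
    interior_xy: np.ndarray | None = None  # interior reference for inward normals

    def __post_init__(self):
        for name, L in self.lengths_mm.items():
            if L <= 0:
                raise ValueError(f"degenerate retinal part {name}")


def partition_retina(geom: SliceGeometry, landmarks: dict | None = None) -> PartitionedContour:
    """Split the retina into the four parts bounded by the landmarks.

    Per side, the posterior part runs from the posterior pole (contour
    intersection of the pupillary axis) to the equator, and the anterior
    part from the equator to the ora serrata; retina anterior to the ora is
    excluded.
    """
    if landmarks is None:
        landmarks = place_landmarks(geom)
    hits = line_intersections(geom.contour, geom.axis_point, geom.axis_dir)
    post = [p for p in hits if float((p - geom.axis_point) @ geom.axis_dir) < 0]
    if not post:
        raise ValueError("pupillary axis does not intersect the contour posteriorly")
    pole = post[int(np.argmax([np.linalg.norm(p - geom.axis_point) for p in post]))]
    s_pole = project_point(geom.contour, pole)
    L = contour_length(geom.contour)

    parts, lengths = {}, {}
    for side, tag in (("superior", "superior"), ("inferior", "inferior")):
        d = landmarks["direction"][side]
        s_l = landmarks["s"][f"limbus_{side}"]
        s_o = landmarks["s"][f"ora_{side}"]
        s_e = landmarks["s"][f"equator_{side}"]
        off_o = (d * (s_o - s_l)) % L
        off_e = (d * (s_e - s_l)) % L
        off_p = (d * (s_pole - s_l)) % L
        if not off_o < off_e < off_p:
            raise ValueError(f"landmarks out of order along the {side} contour")
        parts[f"{tag}_posterior"] = extract_arc(geom.contour, s_pole, s_e, -d)
        parts[f"{tag}_anterior"] = extract_arc(geom.contour, s_e, s_o, -d)
        lengths[f"{tag}_posterior"] = arc_span(geom.contour, s_pole, s_e, -d)
        lengths[f"{tag}_anterior"] = arc_span(geom.contour, s_e, s_o, -d)
    return PartitionedContour(parts, lengths, landmarks, np.asarray(pole),
                              interior_xy=geom.contour.mean(axis=0))


def _resample(polyline: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(math.ceil(total / step)), 2)
    s = (np.arange(n) + 0.5) * total / n  # midpoints of n equal arc bins
    x = np.interp(s, cum, polyline[:, 0])
    y = np.interp(s, cum, polyline[:, 1])
    return np.column_stack([x, y])


def _contact_fraction(vals: np.ndarray, level: float, win: int) -> float:
    """Contacting fraction of a probed intensity profile.

    Samples below ``level`` (the plateau midpoint) are gas.  Each
    gas/fluid transition is then re-localized at the nearby peak of the
    profile gradient: when the meniscus meets the wall obliquely the
    blurred transition is asymmetric and the level crossing drifts off the
    edge, while the gradient extremum stays on it.
    """
    n = vals.size
    gas = vals <= level
    if gas.all():
        return 1.0
    if not gas.any():
        return 0.0
    grad = np.gradient(np.asarray(vals, dtype=float))
    # Sub-sample boundary positions, one per transition.  The search
    # window is clipped at neighbouring transitions, and the gradient sign
    # must match the transition direction so a nearby opposite edge cannot
    # capture it.
    trans = np.nonzero(gas[:-1] != gas[1:])[0]
    cuts = []
    for t_idx, i in enumerate(trans):
        lo_lim = 0 if t_idx == 0 else (trans[t_idx - 1] + i) // 2 + 1
        hi_lim = n if t_idx == len(trans) - 1 else (i + trans[t_idx + 1]) // 2 + 1
        j0, j1 = max(i - win, lo_lim), min(i + win + 1, hi_lim)
        into_gas = bool(gas[i + 1])
        seg = grad[j0:j1]
        j = j0 + int(np.argmin(seg) if into_gas else np.argmax(seg))
        if 0 < j < n - 1:
            denom = grad[j - 1] - 2.0 * grad[j] + grad[j + 1]
            off = 0.5 * (grad[j - 1] - grad[j + 1]) / denom if denom != 0 else 0.0
            pos = j + float(np.clip(off, -1.0, 1.0))
        else:
            pos = i + 0.5
        cuts.append((pos, into_gas))  # True: fluid -> gas
    cuts.sort()
    total = 0.0
    start = 0.0 if gas[0] else None
    for pos, into_gas in cuts:
        if into_gas:
            if start is None:
                start = pos
        else:
            if start is not None:
                total += max(pos - start, 0.0)
                start = None
    if start is not None:
        total += (n - 1) - start
    return float(np.clip(total / (n - 1), 0.0, 1.0))


def measure_contact(
    partition: PartitionedContour,
    gas_mask: np.ndarray,
    pixel_spacing_mm: float,
    tolerance_px: float = 1.5,
    step_mm: float = 0.05,
    posture: str | None = None,
    case_id=None,
    image: np.ndarray | None = None,
    threshold: float | None = None,
) -> ContactRateResult:
    """Gas-contact length and rate per retinal part.

    A retinal point is in contact when gas lies within ``tolerance_px``
    along its inward normal (the fluid film between gas and retina is
    unresolvable at this pixel size).  Probes step inward in half-pixel
    increments up to the tolerance; the probe is deliberately directional,
    because an isotropic distance would also spread contact tangentially
    along the wall past the meniscus ends.

    When the slice ``image`` and its fluid ``threshold`` are supplied, gas
    at the probe point is decided from the bilinearly interpolated
    intensity (inside the cavity everything non-gas is bright fluid), at a
    single half-pixel probe depth.  The decision level is the midpoint of
    the gas and fluid plateau intensities sampled along the whole retina at
    that depth: blur darkens the near-wall intensity of both classes alike
    (the scleral rim bleeds in), so a fixed global threshold would migrate
    the detected meniscus ends into the fluid, while the local midpoint
    crossing stays put.  If only one class is present along the retina, the
    supplied segmentation threshold decides.  Without an image, the boolean
    gas mask is interpolated with half-coverage as the boundary.  Contact
    length is the contacting fraction of equally spaced samples times the
    part length; an empty gas mask yields all-zero rates.
    """
    dx = pixel_spacing_mm
    part_len, contact_len, rate = {}, {}, {}
    has_gas = bool(gas_mask.any())
    use_image = image is not None and threshold is not None
    field = image.astype(np.float32) if use_image else gas_mask.astype(np.float32)
    if partition.interior_xy is not None:
        centroid = np.asarray(partition.interior_xy, dtype=float)
    else:
        centroid = np.mean(np.vstack(list(partition.parts.values())), axis=0)

    def probe_values(poly, depth):
        pts = _resample(poly, step_mm)
        inward = centroid[None, :] - pts
        inward /= np.linalg.norm(inward, axis=1, keepdims=True)
        probe = pts + depth * inward
        return map_coordinates(
            field, [probe[:, 1] / dx, probe[:, 0] / dx], order=1, mode="nearest"
        )

    level = None
    if use_image and has_gas:
        all_vals = np.concatenate(
            [probe_values(partition.parts[n], 0.5 * dx) for n in PART_NAMES]
        )
        lo, hi = np.percentile(all_vals, [5, 95])
        # Midpoint of the two plateaus when both classes are present.
        level = (lo + hi) / 2.0 if hi - lo > 40 else threshold
    win = max(int(round(2.0 * dx / step_mm)), 2)
    depths = np.arange(0.5, tolerance_px + 1e-9, 0.5) * dx
    for name in PART_NAMES:
        poly = partition.parts[name]
        length = partition.lengths_mm[name]
        if not has_gas:
            frac = 0.0
        elif use_image:
            frac = _contact_fraction(probe_values(poly, 0.5 * dx), level, win)
        else:
            pts = _resample(poly, step_mm)
            inward = centroid[None, :] - pts
            inward /= np.linalg.norm(inward, axis=1, keepdims=True)
            hit = np.zeros(len(pts), dtype=bool)
            for depth in depths:
                probe = pts + depth * inward
                vals = map_coordinates(
                    field, [probe[:, 1] / dx, probe[:, 0] / dx], order=1, mode="nearest"
                )
                hit |= vals >= 0.5
            frac = float(np.mean(hit))
        part_len[name] = length
        contact_len[name] = frac * length
        rate[name] = 100.0 * frac
    return ContactRateResult(part_len, contact_len, rate, posture=posture, case_id=case_id)


def locate_meniscus(
    image: np.ndarray,
    threshold: float,
    circle_xy_mm,
    circle_r_mm: float,
    pixel_spacing_mm: float,
) -> tuple[float, bool] | None:
    """Sub-pixel height of the flat gas-fluid interface on one slice.

    The meniscus of a large intraocular bubble is flat and perpendicular to
    gravity, i.e. horizontal in these images.  For every image column well
    inside the cavity (|x - cx| < 0.75 r, wall regions excluded) the
    vertical intensity profile is a single blurred fluid/gas step; its
    crossing of the per-column plateau midpoint is found to sub-pixel
    precision, and the interface height is the median over columns, robust
    to noise and stray columns.  Returns ``(y_mm, gas_is_up)`` in image
    coordinates, or ``None`` when no interface is found (all gas or all
    fluid).
    """
    dx = pixel_spacing_mm
    cx, cy = circle_xy_mm
    img = np.asarray(image, dtype=float)
    half_w = 0.75 * circle_r_mm
    half_h = 0.9 * circle_r_mm
    cols = np.arange(img.shape[1]) * dx
    use_cols = np.nonzero(np.abs(cols - cx) < half_w)[0]
    ys, gas_up_votes = [], []
    for j in use_cols:
        span = math.sqrt(max(circle_r_mm**2 - (cols[j] - cx) ** 2, 0.0))
        span = min(span - 2.0 * dx, half_h)
        if span <= 2.0 * dx:
            continue
        r0 = int(math.ceil((cy - span) / dx))
        r1 = int(math.floor((cy + span) / dx))
        prof = img[r0 : r1 + 1, j]
        if prof.size < 6:
            continue
        lo, hi = float(prof.min()), float(prof.max())
        if hi - lo < 60:  # single class in this column
            continue
        level = (lo + hi) / 2.0
        s = prof - level
        crossings = np.nonzero((s[:-1] > 0) != (s[1:] > 0))[0]
        if len(crossings) != 1:
            continue
        i = crossings[0]
        frac = s[i] / (s[i] - s[i + 1])
        ys.append((r0 + i + frac) * dx)
        gas_up_votes.append(prof[0] < prof[-1])  # dark (gas) at the top?
    if len(ys) < 5:
        return None
    gas_up = sum(gas_up_votes) > len(gas_up_votes) / 2
    return float(np.median(ys)), bool(gas_up)


def measure_contact_plane(
    partition: PartitionedContour,
    meniscus_y_mm: float,
    gas_up: bool,
    step_mm: float = 0.02,
    posture: str | None = None,
    case_id=None,
) -> ContactRateResult:
    """Contact rates from the measured flat meniscus: a side-of-plane test.

    A retinal point is in contact when it lies on the gas side of the
    measured horizontal interface (points exactly on the interface count
    as contact).  With a flat meniscus this is exact up to the accuracy of
    the measured contour and interface height, and free of the probe-depth
    and edge-blur biases of mask probing.
    """
    part_len, contact_len, rate = {}, {}, {}
    for name in PART_NAMES:
        poly = partition.parts[name]
        length = partition.lengths_mm[name]
        pts = _resample(poly, step_mm)
        if gas_up:
            hit = pts[:, 1] <= meniscus_y_mm  # image y grows downward
        else:
            hit = pts[:, 1] >= meniscus_y_mm
        frac = float(np.mean(hit))
        part_len[name] = length
        contact_len[name] = frac * length
        rate[name] = 100.0 * frac
    return ContactRateResult(part_len, contact_len, rate, posture=posture, case_id=case_id)


def axis_from_angle_points(angle_superior, angle_inferior, interior_point):
    """Pupillary axis from the two anterior-chamber angle landmarks.

    The axis is the perpendicular bisector of the angle-angle chord,
    oriented anteriorly (away from the globe interior); the superior
    direction points from the chord midpoint toward the superior angle.
    """
    a_s = np.asarray(angle_superior, dtype=float)
    a_i = np.asarray(angle_inferior, dtype=float)
    mid = (a_s + a_i) / 2.0
    chord = a_s - a_i
    n = np.linalg.norm(chord)
    if n == 0:
        raise ValueError("angle landmarks coincide; axis undefined")
    sup = chord / n
    axis = np.array([-sup[1], sup[0]])
    if float(axis @ (mid - np.asarray(interior_point, dtype=float))) < 0:
        axis = -axis
    return mid, axis, sup


def measure_supraduction(axis_dir, posture: str) -> SupraductionAngle:
    """Signed angle of the pupillary axis to the gravity-perpendicular line.

    In image coordinates the anti-gravity direction is ``(0, -1)`` and
    head-superior is ``(1, 0)``.  The reference (perpendicular-to-ground)
    direction is anterior-up in supine and anterior-down in prone, so
    supraduction is positive in both postures when the eye rotates toward
    head-superior.
    """
    a = np.asarray(axis_dir, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("pupillary axis direction undefined")
    a = a / n
    up = np.array([0.0, -1.0])
    head = np.array([1.0, 0.0])
    ref = up if posture == "supine" else -up
    if posture not in ("supine", "prone"):
        raise ValueError(f"posture must be 'prone' or 'supine', got {posture!r}")
    deg = math.degrees(math.atan2(float(a @ head), float(a @ ref)))
    return SupraductionAngle(deg, posture)
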