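"""Closed-form geometry of a tamponade gas bubble inside the vitreous cavity.

The model: after vitrectomy the vitreous cavity is approximated as a sphere
of radius ``R``.  A single intraocular gas bubble floats against gravity and
is bounded below by a flat meniscus perpendicular to the gravity vector, so
the gas occupies a spherical cap of height ``h``.  The cap-volume relation

    V_cap = pi * h**2 * (3R - h) / 3

links the gas fill fraction ``f = V_cap / V_sphere`` to the cap height via
the cubic ``h**2 (3R - h) = 4 f R**3``, which is monotone on ``[0, 2R]``.

Retinal gas-contact analysis is carried out on the mid-sagittal great circle
of the globe, mirroring how the measurement is done on a single sagittal
slice: the retina between the posterior pole and the ora serrata is split
into four arcs (superior/inferior x posterior/anterior) by anatomical
landmarks placed at fixed arc distances posterior to the surgical limbus
(7 mm for the ora serrata, 13.5 mm for the equator).  An arc point is in
contact with gas when it lies on the anti-gravity side of the meniscus
plane; contact lengths and rates then follow in closed form from
circle/half-plane intersections.

World frame convention used throughout: ``x`` = head-superior (horizontal
when lying down), ``y`` = mediolateral (out of the sagittal plane), ``z`` =
up (anti-gravity).  Gravity is ``(0, 0, -1)`` unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PART_NAMES",
    "EyeModel",
    "GasBubble",
    "RetinalPartition",
    "ContactRateResult",
    "cap_height_from_fraction",
    "fraction_from_cap_height",
    "meniscus_plane",
    "orient_eye",
    "partition_circle",
    "analytic_contact_rates",
]

#: Order matches the reporting order of the four retinal parts.
PART_NAMES = (
    "superior_posterior",
    "superior_anterior",
    "inferior_posterior",
    "inferior_anterior",
)

# Default arc distances (mm) posterior to the surgical limbus.
ORA_SERRATA_MM = 7.0
EQUATOR_MM = 13.5

# Default axial offset (mm) between axial length and the cavity diameter:
# cornea + anterior chamber structures not part of the vitreous cavity.
ANTERIOR_OFFSET_MM = 1.6

# Default arc distance (mm) from the corneal pole to the surgical limbus
# along the globe surface (half the white-to-white chord mapped to a 12 mm
# globe gives ~6 mm of arc).
LIMBUS_OFFSET_MM = 6.0


def cap_height_from_fraction(f: float, R: float) -> float:
    """Height of a spherical cap holding fraction ``f`` of a sphere's volume.

    Solves ``h**2 (3R - h) = 4 f R**3`` for ``h`` in ``[0, 2R]``.  The cubic
    is strictly monotone on that interval, so the root is unique.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fill fraction must be in [0, 1], got {f}")
    if R <= 0:
        raise ValueError(f"radius must be positive, got {R}")
    if f == 0.0:
        return 0.0
    if f == 1.0:
        return 2.0 * R

    def g(h: float) -> float:
        return h * h * (3.0 * R - h) - 4.0 * f * R**3

    # Float rounding can make g lose its sign change within one ulp of the
    # endpoints for f within ~1e-16 of the limits.
    if g(2.0 * R) <= 0.0:
        return 2.0 * R
    if g(0.0) >= 0.0:
        return 0.0
    return brentq(g, 0.0, 2.0 * R, xtol=1e-13, rtol=8.9e-16)


def fraction_from_cap_height(h: float, R: float) -> float:
    """Volume fraction of a sphere occupied by a cap of height ``h``."""
    if R <= 0:
        raise ValueError(f"radius must be positive, got {R}")
    if not 0.0 <= h <= 2.0 * R + 1e-12:
        raise ValueError(f"cap height must be in [0, 2R], got {h} (R={R})")
    return h * h * (3.0 * R - h) / (4.0 * R**3)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def orient_eye(posture: str, supraduction_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Pupillary-axis and eye-superior unit vectors in the world frame.

    Supraduction is the upward rotation of the eye relative to the line
    perpendicular to the ground: in the supine posture the anterior direction
    points straight up at 0 deg; in the prone posture it points straight
    down.  Positive angles rotate the cornea toward the head-superior
    direction in both postures.
    """
    a = math.radians(supraduction_deg)
    if posture == "supine":
        axis = np.array([math.sin(a), 0.0, math.cos(a)])
        superior = np.array([math.cos(a), 0.0, -math.sin(a)])
    elif posture == "prone":
        axis = np.array([math.sin(a), 0.0, -math.cos(a)])
        superior = np.array([math.cos(a), 0.0, math.sin(a)])
    else:
        raise ValueError(f"posture must be 'prone' or 'supine', got {posture!r}")
    return axis, superior


@dataclass(frozen=True)
class EyeModel:
    """Geometric description of one globe.

    The vitreous cavity is the sphere ``|p - center| <= radius``.  The
    pupillary axis points from the cavity center toward the cornea; the
    superior direction is the eye's head-superior direction, orthogonal to
    the axis within the sagittal plane.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 11.9
    axial_length: float = 25.4
    pupillary_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    superior_dir: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    limbus_offset_mm: float = LIMBUS_OFFSET_MM

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "pupillary_axis", _unit(self.pupillary_axis))
        object.__setattr__(self, "superior_dir", _unit(self.superior_dir))
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.axial_length < 2.0 * self.radius - 1e-9:
            raise ValueError("axial length must be at least the cavity diameter")
        if abs(float(self.pupillary_axis @ self.superior_dir)) > 1e-8:
            raise ValueError("superior_dir must be orthogonal to pupillary_axis")
        if not 0 < self.limbus_offset_mm < math.pi * self.radius:
            raise ValueError("limbus offset must lie on the anterior hemisphere arc")

    @classmethod
    def from_clinical(
        cls,
        axial_length_mm: float,
        posture: str = "supine",
        supraduction_deg: float = 0.0,
        anterior_offset_mm: float = ANTERIOR_OFFSET_MM,
        limbus_offset_mm: float = LIMBUS_OFFSET_MM,
        center=(0.0, 0.0, 0.0),
    ) -> "EyeModel":
        """Build an oriented eye from an axial length and a posture.

        The cavity radius is ``(axial_length - anterior_offset) / 2``: the
        axial length includes the cornea and anterior chamber, which are not
        part of the vitreous cavity.
        """
        axis, superior = orient_eye(posture, supraduction_deg)
        radius = (axial_length_mm - anterior_offset_mm) / 2.0
        return cls(
            center=np.asarray(center, dtype=float),
            radius=radius,
            axial_length=axial_length_mm,
            pupillary_axis=axis,
            superior_dir=superior,
            limbus_offset_mm=limbus_offset_mm,
        )

    def rotated(self, posture: str, supraduction_deg: float) -> "EyeModel":
        axis, superior = orient_eye(posture, supraduction_deg)
        return replace(self, pupillary_axis=axis, superior_dir=superior)


@dataclass(frozen=True)
class GasBubble:
    """A gas bubble described by its fill fraction and the gravity direction.

    The bubble resolves to a spherical cap on the anti-gravity side of the
    cavity; ``cap_height_mm(R)`` gives the cap height for a cavity of radius
    ``R``.
    """

    fill_fraction: float
    gravity_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))

    def __post_init__(self):
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise ValueError("fill_fraction must be in [0, 1]")
        object.__setattr__(self, "gravity_dir", _unit(self.gravity_dir))

    def cap_height_mm(self, radius: float) -> float:
        return cap_height_from_fraction(self.fill_fraction, radius)


def meniscus_plane(eye: EyeModel, bubble: GasBubble) -> tuple[np.ndarray, np.ndarray]:
    """Plane of the flat gas-fluid interface, as ``(point, normal)``.

    The normal points toward the gas (anti-gravity) side.  The plane sits at
    signed distance ``R - h`` from the cavity center along the normal, so
    that the cap above it holds the bubble's volume.
    """
    h = bubble.cap_height_mm(eye.radius)
    normal = -bubble.gravity_dir
    point = eye.center + (eye.radius - h) * normal
    return point, normal


@dataclass(frozen=True)
class RetinalPartition:
    """Four retinal arcs on the mid-sagittal circle, in angular coordinates.

    Angles are polar angles from the anterior pole (the pupillary-axis
    direction), in radians; each part is ``(theta_start, theta_end, side)``
    with ``side`` +1 for superior, -1 for inferior, and
    ``theta_start < theta_end``.
    """

    radius: float
    limbus_angle: float
    ora_angle: float
    equator_angle: float
    parts: dict

    def part_length_mm(self, name: str) -> float:
        t0, t1, _ = self.parts[name]
        return self.radius * (t1 - t0)


def partition_circle(
    radius: float,
    limbus_offset_mm: float = LIMBUS_OFFSET_MM,
    ora_mm: float = ORA_SERRATA_MM,
    equator_mm: float = EQUATOR_MM,
) -> RetinalPartition:
    """Place the four-part retinal partition on a circle of given radius.

    The ora serrata and equator are placed ``ora_mm`` and ``equator_mm`` of
    arc posterior to the limbus; the posterior parts run from the posterior
    pole to the equator, the anterior parts from the equator to the ora.
    """
    t_limbus = limbus_offset_mm / radius
    t_ora = (limbus_offset_mm + ora_mm) / radius
    t_eq = (limbus_offset_mm + equator_mm) / radius
    if not t_limbus < t_ora < t_eq < math.pi:
        raise ValueError("landmarks do not fit on the hemisphere anterior to the pole")
    parts = {
        "superior_posterior": (t_eq, math.pi, +1),
        "superior_anterior": (t_ora, t_eq, +1),
        "inferior_posterior": (t_eq, math.pi, -1),
        "inferior_anterior": (t_ora, t_eq, -1),
    }
    for name, (a, b, _) in parts.items():
        if b - a <= 0:
            raise ValueError(f"degenerate retinal part {name}")
    return RetinalPartition(radius, t_limbus, t_ora, t_eq, parts)


@dataclass
class ContactRateResult:
    """Per-part arc lengths, gas-contact lengths and contact rates (%)."""

    part_length_mm: dict
    contact_length_mm: dict
    rate_pct: dict
    posture: str | None = None
    case_id: object = None

    def __post_init__(self):
        for name in self.part_length_mm:
            pl = self.part_length_mm[name]
            cl = self.contact_length_mm[name]
            if not 0.0 <= cl <= pl + 1e-9:
                raise ValueError(f"contact length out of range for {name}")

    def as_rows(self):
        return [
            {
                "case_id": self.case_id,
                "posture": self.posture,
                "part": name,
                "part_length_mm": self.part_length_mm[name],
                "contact_length_mm": self.contact_length_mm[name],
                "rate_pct": self.rate_pct[name],
            }
            for name in PART_NAMES
        ]


def _interval_overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _arc_contact_measure(t0: float, t1: float, phi: float, half_width: float) -> float:
    """Angular measure of ``[t0, t1]`` inside ``[phi - hw, phi + hw]`` mod 2pi."""
    total = 0.0
    for k in (-1, 0, 1):
        total += _interval_overlap(t0, t1, phi - half_width + 2 * math.pi * k,
                                   phi + half_width + 2 * math.pi * k)
    return total


def analytic_contact_rates(
    eye: EyeModel,
    bubble: GasBubble,
    partition: RetinalPartition | None = None,
    posture: str | None = None,
    case_id=None,
) -> ContactRateResult:
    """Closed-form gas-contact rates of the four retinal parts.

    A point of the mid-sagittal circle at polar angle ``theta`` on side
    ``sigma`` is ``p = c + R (cos(theta) a + sigma sin(theta) s)``; it is in
    contact with gas when ``(p - c) . u >= R - h`` with ``u`` the
    anti-gravity unit vector.  Writing ``A = a.u`` and ``B = sigma s.u``
    this becomes ``M cos(theta - phi) >= 1 - h/R`` with ``M = hypot(A, B)``
    and ``phi = atan2(B, A)`` -- an arc of the circle, intersected here with
    each retinal part.  Points exactly on the meniscus plane count as
    contact (a measure-zero convention, fixed for determinism).
    """
    if partition is None:
        partition = partition_circle(eye.radius, eye.limbus_offset_mm)
    if abs(partition.radius - eye.radius) > 1e-9:
        raise ValueError("partition radius does not match the eye")
    R = eye.radius
    h = bubble.cap_height_mm(R)
    up = -bubble.gravity_dir
    A = float(eye.pupillary_axis @ up)
    Bs = float(eye.superior_dir @ up)
    c = 1.0 - h / R

    part_len, contact_len, rate = {}, {}, {}
    for name, (t0, t1, sigma) in partition.parts.items():
        B = sigma * Bs
        M = math.hypot(A, B)
        length = R * (t1 - t0)
        if length <= 0:
            raise ValueError(f"degenerate retinal part {name}")
        if M < 1e-15:
            # Gravity orthogonal to the slice plane: whole circle on one side.
            measure = (t1 - t0) if c <= 0 else 0.0
        elif c <= -M:
            measure = t1 - t0
        elif c > M:
            measure = 0.0
        else:
            phi = math.atan2(B, A)
            half_width = math.acos(max(-1.0, min(1.0, c / M)))
            measure = _arc_contact_measure(t0, t1, phi, half_width)
        contact = R * measure
        part_len[name] = length
        contact_len[name] = min(contact, length)
        rate[name] = 100.0 * contact_len[name] / length
    return ContactRateResult(part_len, contact_len, rate, posture=posture, case_id=case_id)
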