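"""Synthetic sagittal MRI-like slice stacks of a gas-filled post-vitrectomy eye.

The phantom emulates the appearance of a T2-weighted sagittal acquisition of
an eye four days after vitrectomy with gas tamponade: intraocular fluid is
bright, the gas bubble and background air are dark, and the scleral wall is
an intermediate-intensity rim.  A schematic anterior segment (iris/angle
band and a small bright anterior chamber) is drawn anterior to the cavity so
that limbus localization can be exercised.  Acquisition geometry follows a
140 mm field of view on a 320x320 matrix (0.4375 mm pixels) with 3.0 mm
slices and a 0.5 mm gap.  Motion-robust acquisition is emulated only as
Gaussian blur plus noise; no k-space physics is simulated.

Every stack carries a ground-truth sidecar: per-slice cavity and gas masks,
the true fill fraction and supraduction angle, and landmark coordinates on
the central slice, all derived from the closed-form geometry in
:mod:`oculogas.geometry`.

Image coordinate convention: columns increase toward head-superior, rows
increase downward (toward gravity); slices are stacked along the
mediolateral axis.  A world point ``(x, y, z)`` maps to the pixel
``col = cx + x / dx``, ``row = cy - z / dx`` on the slice at mediolateral
offset ``y``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .geometry import EyeModel, GasBubble, orient_eye

__all__ = [
    "ImagingParams",
    "ImageStack",
    "GroundTruth",
    "Scenario",
    "render_stack",
    "cohort_from_table3",
]

# Nominal tissue intensities (arbitrary units on an 8-bit scale).
I_BACKGROUND = 20.0
I_GAS = 20.0
I_SCLERA = 60.0
I_FLUID = 200.0
I_AQUEOUS = 180.0

SCLERA_THICKNESS_MM = 1.0
IRIS_BAND_MM = 0.8
ANTERIOR_CHAMBER_DEPTH_MM = 2.5


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition-like parameters of the synthetic stack.

    Defaults reproduce the acquisition geometry of the study setting: FOV
    140 mm, matrix 320x320, 3.0 mm slices with a 0.5 mm intersection gap.
    ``noise_sd`` and ``blur_sigma_px`` stand in for thermal noise and the
    effective point-spread of the motion-robust reconstruction.
    """

    fov_mm: float = 140.0
    matrix: int = 320
    slice_thickness_mm: float = 3.0
    slice_gap_mm: float = 0.5
    n_slices: int = 11
    noise_sd: float = 10.0
    blur_sigma_px: float = 1.0
    supersample: int = 4
    seed: int = 0

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    def __post_init__(self):
        if self.fov_mm <= 0 or self.matrix <= 0:
            raise ValueError("FOV and matrix must be positive")
        if self.slice_thickness_mm + self.slice_gap_mm <= 0:
            raise ValueError("slice spacing must be positive")
        if self.supersample < 1:
            raise ValueError("supersample factor must be >= 1")


@dataclass
class ImageStack:
    """Ordered grayscale slices with pixel and slice spacing metadata."""

    data: np.ndarray  # (n_slices, H, W) uint8
    pixel_spacing_mm: float
    slice_spacing_mm: float
    slice_offsets_mm: np.ndarray  # mediolateral offset of each slice
    orientation: str = "sagittal"

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("stack data must be (n_slices, H, W)")
        if self.pixel_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def save(self, tiff_path, sidecar: "GroundTruth | None" = None):
        tiff_path = Path(tiff_path)
        tifffile.imwrite(tiff_path, self.data)
        meta = {
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "slice_spacing_mm": self.slice_spacing_mm,
            "slice_offsets_mm": list(map(float, self.slice_offsets_mm)),
            "orientation": self.orientation,
        }
        if sidecar is not None:
            meta["ground_truth"] = sidecar.to_dict()
        with open(tiff_path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, tiff_path) -> tuple["ImageStack", dict | None]:
        tiff_path = Path(tiff_path)
        data = tifffile.imread(tiff_path)
        if data.ndim == 2:
            data = data[None]
        with open(tiff_path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        stack = cls(
            data=data,
            pixel_spacing_mm=meta["pixel_spacing_mm"],
            slice_spacing_mm=meta["slice_spacing_mm"],
            slice_offsets_mm=np.asarray(meta["slice_offsets_mm"]),
            orientation=meta.get("orientation", "sagittal"),
        )
        return stack, meta.get("ground_truth")


@dataclass
class GroundTruth:
    """Closed-form truth accompanying a rendered stack.

    Landmark coordinates are for the central slice, in image millimetres
    (``x = col * dx``, ``y = row * dx``) with sub-pixel precision.
    """

    fill_fraction: float
    supraduction_deg: float
    posture: str
    cap_height_mm: float
    radius_mm: float
    axial_length_mm: float
    center_xy_mm: tuple
    central_slice: int
    axis_dir_xy: tuple  # pupillary axis in image coords (unit)
    superior_dir_xy: tuple
    landmarks_xy_mm: dict  # angle/limbus sup+inf, anterior/posterior pole
    pixel_spacing_mm: float
    cavity_masks: np.ndarray | None = None  # (n, H, W) bool
    gas_masks: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k not in ("cavity_masks", "gas_masks")}
        d["center_xy_mm"] = list(map(float, self.center_xy_mm))
        d["axis_dir_xy"] = list(map(float, self.axis_dir_xy))
        d["superior_dir_xy"] = list(map(float, self.superior_dir_xy))
        d["landmarks_xy_mm"] = {k: list(map(float, v)) for k, v in self.landmarks_xy_mm.items()}
        return d


def _block_mean(a: np.ndarray, ss: int) -> np.ndarray:
    h, w = a.shape
    return a.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))


def render_stack(
    eye: EyeModel,
    bubble: GasBubble,
    params: ImagingParams,
    posture: str,
    supraduction_deg: float,
) -> tuple[ImageStack, GroundTruth]:
    """Render a sagittal stack of one eye and its ground-truth sidecar.

    The eye is re-oriented from the posture and signed supraduction angle
    (positive = supraduction); the world gravity direction is always
    straight down, so the bubble's gravity must be ``(0, 0, -1)``.
    Rendering is deterministic for a fixed ``params.seed``.
    """
    if abs(supraduction_deg) >= 45:
        raise ValueError("supraduction angle out of the modelled range (|angle| < 45 deg)")
    if not np.allclose(bubble.gravity_dir, [0.0, 0.0, -1.0]):
        raise ValueError("the renderer assumes gravity along -z in the world frame")
    R = eye.radius
    if 2.0 * (R + SCLERA_THICKNESS_MM + 2.0) > params.fov_mm:
        raise ValueError("eye does not fit in the field of view")

    axis3, sup3 = orient_eye(posture, supraduction_deg)
    # In-plane components (x = head-superior, z = up); y is mediolateral.
    ax = np.array([axis3[0], axis3[2]])
    sx = np.array([sup3[0], sup3[2]])
    h = bubble.cap_height_mm(R)
    z_plane = R - h  # gas occupies z >= z_plane (relative to eye center)

    m, ss = params.matrix, params.supersample
    dx = params.pixel_spacing_mm
    cx = cy = (m - 1) / 2.0  # eye center at the image center pixel
    # Subpixel world coordinates.
    idx = (np.arange(m * ss) + 0.5) / ss - 0.5
    X = (idx[None, :] - cx) * dx          # world x (head-superior), varies with col
    Z = (cy - idx[:, None]) * dx          # world z (up), varies with row
    Xg, Zg = np.broadcast_arrays(X, Z)
    r2_inplane = Xg * Xg + Zg * Zg
    U = Xg * ax[0] + Zg * ax[1]           # axial coordinate along pupillary axis
    V = Xg * sx[0] + Zg * sx[1]           # transverse coordinate toward superior

    theta_l = eye.limbus_offset_mm / R
    x_ir = R * math.cos(theta_l)          # axial position of the iris/angle plane
    w_l = R * math.sin(theta_l)           # half-chord of the limbus plane

    n = params.n_slices
    offsets = (np.arange(n) - (n - 1) / 2.0) * params.slice_spacing_mm
    rng = np.random.default_rng(params.seed)

    slices = np.empty((n, m, m), dtype=np.uint8)
    cavity_masks = np.empty((n, m, m), dtype=bool)
    gas_masks = np.empty((n, m, m), dtype=bool)
    R_out2 = (R + SCLERA_THICKNESS_MM) ** 2
    for k, d in enumerate(offsets):
        dist2 = r2_inplane + d * d
        cavity = dist2 <= R * R
        shell = (~cavity) & (dist2 <= R_out2)
        gas = cavity & (Zg >= z_plane)
        img = np.full((m * ss, m * ss), I_BACKGROUND, dtype=np.float32)
        img[shell] = I_SCLERA
        img[cavity] = I_FLUID
        img[gas] = I_GAS
        # Schematic anterior segment, entirely anterior to the cavity sphere:
        # a dark iris/IOL band at the limbus plane and a bright anterior
        # chamber tapering toward the cornea.
        rho2 = V * V + d * d  # distance^2 from the pupillary axis
        outside = dist2 > R_out2  # keep the scleral rim intact
        band = outside & (U >= x_ir) & (U <= x_ir + IRIS_BAND_MM) & (rho2 <= (w_l + 1.0) ** 2)
        img[band] = I_GAS
        u_ac = U - (x_ir + IRIS_BAND_MM)
        taper = np.clip(1.0 - u_ac / ANTERIOR_CHAMBER_DEPTH_MM, 0.0, 1.0)
        ac = outside & (u_ac > 0) & (u_ac <= ANTERIOR_CHAMBER_DEPTH_MM) \
            & (rho2 <= (np.maximum(w_l - 0.5, 0.0) * taper) ** 2)
        img[ac] = I_AQUEOUS

        pix = _block_mean(img, ss)
        if params.noise_sd > 0:
            pix = pix + rng.normal(0.0, params.noise_sd, size=pix.shape)
        if params.blur_sigma_px > 0:
            pix = gaussian_filter(pix, params.blur_sigma_px)
        slices[k] = np.clip(np.rint(pix), 0, 255).astype(np.uint8)
        cavity_masks[k] = _block_mean(cavity.astype(np.float32), ss) >= 0.5
        gas_masks[k] = _block_mean(gas.astype(np.float32), ss) >= 0.5

    stack = ImageStack(
        data=slices,
        pixel_spacing_mm=dx,
        slice_spacing_mm=params.slice_spacing_mm,
        slice_offsets_mm=offsets,
    )

    def to_image_xy(p2_world: np.ndarray) -> tuple:
        # world (x, z) relative to eye center -> image mm (x = col*dx, y = row*dx)
        return (float(p2_world[0] + cx * dx), float(cy * dx - p2_world[1]))

    landmarks = {
        "angle_superior": to_image_xy(x_ir * ax + w_l * sx),
        "angle_inferior": to_image_xy(x_ir * ax - w_l * sx),
        "limbus_superior": to_image_xy(x_ir * ax + w_l * sx),
        "limbus_inferior": to_image_xy(x_ir * ax - w_l * sx),
        "anterior_pole": to_image_xy(R * ax),
        "posterior_pole": to_image_xy(-R * ax),
    }
    axis_img = (float(ax[0]), float(-ax[1]))  # image y is world -z
    sup_img = (float(sx[0]), float(-sx[1]))
    truth = GroundTruth(
        fill_fraction=bubble.fill_fraction,
        supraduction_deg=supraduction_deg,
        posture=posture,
        cap_height_mm=h,
        radius_mm=R,
        axial_length_mm=eye.axial_length,
        center_xy_mm=(cx * dx, cy * dx),
        central_slice=int(np.argmin(np.abs(offsets))),
        axis_dir_xy=axis_img,
        superior_dir_xy=sup_img,
        landmarks_xy_mm=landmarks,
        pixel_spacing_mm=dx,
        cavity_masks=cavity_masks,
        gas_masks=gas_masks,
    )
    return stack, truth


@dataclass(frozen=True)
class Scenario:
    """One phantom condition: a printed case in one posture."""

    case_id: int
    posture: str
    fill_fraction: float
    supraduction_deg: float
    axial_length_mm: float


def cohort_from_table3(table3: pd.DataFrame, table1: pd.DataFrame) -> list[Scenario]:
    """Phantom scenarios for the printed cohort: 8 cases x 2 postures.

    Gas volume percentages and supraduction angles come from the per-case
    gas/angle table; axial lengths come from the patient-characteristics
    table.
    """
    required3 = {"case", "gas_volume_pct_prone", "gas_volume_pct_supine",
                 "angle_deg_prone", "angle_deg_supine"}
    if not required3 <= set(table3.columns):
        raise ValueError(f"gas/angle table missing columns {sorted(required3 - set(table3.columns))}")
    if not {"case", "axial_length_mm"} <= set(table1.columns):
        raise ValueError("patient table must have 'case' and 'axial_length_mm' columns")
    al = table1.set_index("case")["axial_length_mm"]
    scenarios = []
    for _, row in table3.iterrows():
        case = int(row["case"])
        if case not in al.index:
            raise ValueError(f"case {case} has no axial length entry")
        for posture in ("prone", "supine"):
            gas = float(row[f"gas_volume_pct_{posture}"])
            ang = float(row[f"angle_deg_{posture}"])
            if not 0.0 <= gas <= 100.0:
                raise ValueError(f"case {case} {posture}: gas volume {gas} out of range")
            scenarios.append(Scenario(case, posture, gas / 100.0, ang, float(al[case])))
    return scenarios
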