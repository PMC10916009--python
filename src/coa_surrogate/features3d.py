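"""Cross-section-stack (3D) training records.

Eighty cross-sectional planes are extracted perpendicular to the centerline
at 4 mm spacing, rasterised at 100 x 100 over a fixed 50 x 50 mm field of
view, anti-alias filtered with a Gaussian (sigma = (s - 1)/2 for a
decimation ratio s) and decimated to 48 x 48.  Scalar features (radius,
radius gradient, flow, mean velocity, pressure) are broadcast as constant
values over the lumen pixels; the three grid-coordinate channels carry the
world position of each pixel.  Everything outside the lumen mask is exactly
zero, and planes beyond the case outlet are entirely empty.

The filtering of in-lumen channels is mask-normalised (filtered channel
divided by the filtered mask) so a constant in-lumen value survives
decimation exactly instead of being dragged toward zero at the lumen edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import CapacityError, ParameterError
from .features1d import radius_gradient
from .geometry import AortaGeometry, FlowBC, assign_flow_profile, resample_by_arc_length
from .oracle import HemodynamicProfile
from .units import MM_M, m3s_to_mls

DEFAULT_N_PLANES = 80
DEFAULT_PLANE_SPACING = 4.0  # mm; maximum admissible length 80 x 4 = 320 mm
SOURCE_RESOLUTION = 100
TARGET_RESOLUTION = 48
FIELD_OF_VIEW_MM = 50.0

INPUT_CHANNELS = ("radius", "radius_gradient", "grid_x", "grid_y", "grid_z", "flow", "v_avg")


@dataclass(frozen=True)
class DecimationSpec:
    """Gaussian anti-alias decimation from source to target resolution."""

    source_resolution: int = SOURCE_RESOLUTION
    target_resolution: int = TARGET_RESOLUTION

    @property
    def ratio(self) -> float:
        return self.source_resolution / self.target_resolution

    @property
    def sigma(self) -> float:
        """Per-axis Gaussian SD, sigma = (s - 1)/2 (~0.54 for 100 -> 48)."""
        return (self.ratio - 1.0) / 2.0

    def __post_init__(self):
        if self.target_resolution >= self.source_resolution:
            raise ParameterError("decimation requires target < source resolution")


@dataclass
class Case3D:
    """One 3D training record: (48, 48, 80, 7) inputs, (48, 48, 80, 1) output."""

    case_id: str
    inputs: np.ndarray
    outputs: np.ndarray
    lumen_mask: np.ndarray  # bool (48, 48, 80)
    n_valid_planes: int
    pressure_scale: float = 1.0  # SD used to scale the output for training

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        self.lumen_mask = np.asarray(self.lumen_mask, dtype=bool)
        s = self.lumen_mask.shape
        if self.inputs.shape != s + (len(INPUT_CHANNELS),):
            raise ParameterError("inputs shape must be mask shape + (7,)")
        if self.outputs.shape != s + (1,):
            raise ParameterError("outputs shape must be mask shape + (1,)")
        if not 0 < self.n_valid_planes <= s[2]:
            raise ParameterError("n_valid_planes out of range")
        out_mask = ~self.lumen_mask
        if np.any(self.inputs[out_mask]) or np.any(self.outputs[out_mask]):
            raise ParameterError("values outside the lumen mask must be zero")
        if np.any(self.lumen_mask[:, :, self.n_valid_planes :]):
            raise ParameterError("planes beyond the outlet must be empty")


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent/normal/binormal frames along a polyline, flip-free."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = ref - (ref @ tangents[0]) * tangents[0]
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(points)):
        n = normals[i - 1] - (normals[i - 1] @ tangents[i]) * tangents[i]
        norm = np.linalg.norm(n)
        if norm < 1e-12:  # degenerate; restart frame
            n = ref - (ref @ tangents[i]) * tangents[i]
            norm = np.linalg.norm(n)
        normals[i] = n / norm
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def _pixel_offsets(resolution: int, fov: float) -> np.ndarray:
    """1D pixel-center offsets (mm) spanning the field of view."""
    pitch = fov / resolution
    return (np.arange(resolution) + 0.5) * pitch - fov / 2.0


def extract_planes(
    geometry: AortaGeometry,
    profile: HemodynamicProfile,
    bc: FlowBC,
    spacing: float = DEFAULT_PLANE_SPACING,
    n_planes: int = DEFAULT_N_PLANES,
    resolution: int = SOURCE_RESOLUTION,
    fov: float = FIELD_OF_VIEW_MM,
) -> tuple[dict[str, np.ndarray], np.ndarray, int]:
    """Rasterise per-feature plane stacks at source resolution.

    Returns ``(channels, lumen_mask, n_valid)`` where each channel is a
    float array (resolution, resolution, n_planes), the mask is boolean of
    the same shape, and ``n_valid`` is the number of in-aorta planes.
    """
    # one plane per spacing-long segment, placed at the segment start: a
    # 100 mm aorta yields 25 planes and 80 planes cover exactly 320 mm
    length = geometry.length
    n_valid = int(np.ceil(length / spacing - 1e-9))
    if n_valid > n_planes:
        raise CapacityError(
            f"case {geometry.case_id} is {length:.0f} mm long, exceeding the "
            f"{n_planes * spacing:.0f} mm capacity of the {n_planes}-plane stack"
        )

    centers = resample_by_arc_length(geometry.centerline_points, spacing)[:n_valid]
    _, normals, binormals = _parallel_transport_frames(centers)

    s_fine = geometry.arc_length()
    s_planes = spacing * np.arange(n_valid)
    r_planes = np.interp(s_planes, s_fine, geometry.radius)
    g_planes = radius_gradient(r_planes, spacing)
    flow_fine = assign_flow_profile(bc.inlet_flow, geometry.branches, geometry.n_points)
    idx_nearest = np.clip(np.round(s_planes / geometry.spacing).astype(int), 0, geometry.n_points - 1)
    flow_planes = m3s_to_mls(flow_fine[idx_nearest])
    v_planes = flow_fine[idx_nearest] / (np.pi * (r_planes * MM_M) ** 2)
    p_planes = np.interp(s_planes, s_fine, profile.pressure)

    off = _pixel_offsets(resolution, fov)
    U, V = np.meshgrid(off, off, indexing="ij")
    rho = np.sqrt(U**2 + V**2)

    shape = (resolution, resolution, n_planes)
    mask = np.zeros(shape, dtype=bool)
    channels = {name: np.zeros(shape) for name in INPUT_CHANNELS + ("pressure",)}
    for k in range(n_valid):
        m = rho <= r_planes[k]
        mask[:, :, k] = m
        world = (
            centers[k][None, None, :]
            + U[..., None] * normals[k][None, None, :]
            + V[..., None] * binormals[k][None, None, :]
        )
        channels["grid_x"][:, :, k] = np.where(m, world[..., 0], 0.0)
        channels["grid_y"][:, :, k] = np.where(m, world[..., 1], 0.0)
        channels["grid_z"][:, :, k] = np.where(m, world[..., 2], 0.0)
        for name, val in (
            ("radius", r_planes[k]),
            ("radius_gradient", g_planes[k]),
            ("flow", flow_planes[k]),
            ("v_avg", v_planes[k]),
            ("pressure", p_planes[k]),
        ):
            channels[name][:, :, k] = np.where(m, val, 0.0)
    return channels, mask, n_valid


def gaussian_decimate(plane: np.ndarray, spec: DecimationSpec = DecimationSpec()) -> np.ndarray:
    """Anti-alias filter then resample one plane to the target resolution."""
    plane = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(plane)):
        raise ParameterError("plane must be finite-valued")
    filtered = gaussian_filter(plane, spec.sigma, mode="reflect", truncate=4.0)
    s = spec.ratio
    tgt = (np.arange(spec.target_resolution) + 0.5) * s - 0.5
    I, J = np.meshgrid(tgt, tgt, indexing="ij")
    return map_coordinates(filtered, [I, J], order=1, mode="nearest")


def _decimate_masked(
    plane: np.ndarray, mask: np.ndarray, spec: DecimationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Mask-normalised decimation; returns (plane48, mask48_bool)."""
    mf = gaussian_decimate(mask.astype(float), spec)
    pf = gaussian_decimate(plane, spec)
    mask48 = mf > 0.5
    out = np.zeros_like(pf)
    out[mask48] = pf[mask48] / mf[mask48]
    return out, mask48


def broadcast_scalars(scalars: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Broadcast one scalar per plane onto the lumen pixels of each plane."""
    scalars = np.asarray(scalars, dtype=float)
    if scalars.shape[0] != mask.shape[2]:
        raise ParameterError("need exactly one scalar per plane")
    return np.where(mask, scalars[None, None, :], 0.0)


def build_case_3d(
    geometry: AortaGeometry,
    bc: FlowBC,
    profile: HemodynamicProfile,
    spacing: float = DEFAULT_PLANE_SPACING,
    n_planes: int = DEFAULT_N_PLANES,
    spec: DecimationSpec = DecimationSpec(),
) -> Case3D:
    """Assemble the decimated (48, 48, 80, *) record for one solved case."""
    channels, mask100, n_valid = extract_planes(
        geometry, profile, bc, spacing, n_planes, spec.source_resolution
    )
    res = spec.target_resolution
    mask48 = np.zeros((res, res, n_planes), dtype=bool)
    inputs = np.zeros((res, res, n_planes, len(INPUT_CHANNELS)))
    outputs = np.zeros((res, res, n_planes, 1))
    for k in range(n_valid):
        m100 = mask100[:, :, k]
        if not m100.any():
            continue
        for c, name in enumerate(INPUT_CHANNELS):
            dec, m48 = _decimate_masked(channels[name][:, :, k], m100, spec)
            inputs[:, :, k, c] = dec
        dec, m48 = _decimate_masked(channels["pressure"][:, :, k], m100, spec)
        outputs[:, :, k, 0] = dec
        mask48[:, :, k] = m48
    # enforce exact zeros outside the decimated mask
    inputs[~mask48] = 0.0
    outputs[~mask48] = 0.0
    sd = float(outputs[mask48].std()) or 1.0
    return Case3D(
        case_id=geometry.case_id,
        inputs=inputs,
        outputs=outputs,
        lumen_mask=mask48,
        n_valid_planes=n_valid,
        pressure_scale=sd,
    )


def planes_to_centerline(pressure: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Average a (H, W, P) or (H, W, P, 1) pressure field over the lumen of
    each plane, returning the per-plane 1D pressure curve.

    Planes with an empty mask yield NaN and should be treated as beyond the
    outlet.
    """
    p = np.asarray(pressure, dtype=float)
    if p.ndim == 4:
        p = p[..., 0]
    mask = np.asarray(mask, dtype=bool)
    if p.shape != mask.shape:
        raise ParameterError("pressure and mask shapes must agree")
    counts = mask.sum(axis=(0, 1))
    sums = np.where(mask, p, 0.0).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
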