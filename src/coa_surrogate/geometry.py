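"""Synthetic aortic geometry and flow boundary conditions.

One case is a discrete centerline (points spaced ``h`` mm apart along arc
length), a per-point inscribed-lumen radius with an optional focal stenosis,
three arch branch outflows modelled as flow sinks, and an inlet flow rate
with the inlet static pressure pinned at 120 mmHg.

The centerline family is an elliptical arch joined C1-continuously to
straight ascending and descending limbs, parameterised by arch height and
width.  Arch morphology is summarised by the height/width ratio: ratios
above a configurable threshold (default 1.0, strict) are labelled *gothic*,
i.e. a tall narrow arch, which carries excess curvature-related pressure
loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .units import mls_to_m3s

INLET_PRESSURE_MMHG: float = 120.0
"""Fixed inlet static pressure (mmHg) anchoring every pressure curve."""

#: discrete-curvature threshold (1/mm) separating straight limbs from the arch
_CURVATURE_EPS = 1e-4


@dataclass(frozen=True)
class BranchSpec:
    """An arch branch modelled purely as a flow sink."""

    attach_index: int
    outflow_fraction: float

    def __post_init__(self):
        if not 0.0 < self.outflow_fraction < 1.0:
            raise ParameterError(
                f"outflow_fraction must be in (0,1), got {self.outflow_fraction}"
            )
        if self.attach_index < 0:
            raise ParameterError("attach_index must be non-negative")


@dataclass(frozen=True)
class FlowBC:
    """Inlet boundary conditions: volumetric flow (m^3/s) at 120 mmHg."""

    inlet_flow: float
    inlet_pressure: float = INLET_PRESSURE_MMHG

    def __post_init__(self):
        if self.inlet_flow <= 0:
            raise ParameterError(f"inlet_flow must be > 0, got {self.inlet_flow}")
        if self.inlet_pressure != INLET_PRESSURE_MMHG:
            raise ParameterError(
                f"inlet_pressure is fixed at {INLET_PRESSURE_MMHG} mmHg"
            )


@dataclass
class AortaGeometry:
    """Discrete centerline geometry of one case.

    ``centerline_points`` are case-local coordinates in mm (inlet at the
    origin, inlet tangent along +z); ``radius`` is the per-point lumen
    radius in mm.  ``arch_start_index``/``arch_end_index`` delimit the
    curved arch segment when known (set by the generator).
    """

    case_id: str
    centerline_points: np.ndarray  # (n, 3) mm
    spacing: float  # mm, arc length between consecutive points
    radius: np.ndarray  # (n,) mm
    branches: list[BranchSpec] = field(default_factory=list)
    arch_height: float = 0.0  # mm (vertical diameter of the elliptical arch)
    arch_width: float = 0.0  # mm (ascending-to-descending distance)
    arch_start_index: int | None = None
    arch_end_index: int | None = None

    def __post_init__(self):
        self.centerline_points = np.asarray(self.centerline_points, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        n = self.n_points
        if n < 10:
            raise ParameterError(f"need at least 10 centerline points, got {n}")
        if self.radius.shape != (n,):
            raise ParameterError("radius length must match point count")
        if np.any(self.radius <= 0):
            raise ParameterError("all radii must be positive")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        frac = sum(b.outflow_fraction for b in self.branches)
        if frac >= 1.0:
            raise ParameterError(
                f"branch outflow fractions must sum to < 1, got {frac}"
            )
        idx = [b.attach_index for b in self.branches]
        if any(j <= i for i, j in zip(idx, idx[1:])):
            raise ParameterError("branch attach indices must be strictly increasing")
        if idx and idx[-1] >= n:
            raise ParameterError("branch attach index beyond centerline")
        if self.arch_start_index is not None and self.arch_end_index is not None:
            for b in self.branches:
                if not self.arch_start_index <= b.attach_index <= self.arch_end_index:
                    raise ParameterError("branches must attach on the arch segment")

    @property
    def n_points(self) -> int:
        return len(self.centerline_points)

    @property
    def stenosis_index(self) -> int:
        """Index of the minimum lumen radius."""
        return int(np.argmin(self.radius))

    @property
    def length(self) -> float:
        """Total arc length in mm."""
        return self.spacing * (self.n_points - 1)

    def arc_length(self) -> np.ndarray:
        """Per-point arc-length coordinate (mm)."""
        return self.spacing * np.arange(self.n_points)


def straight_centerline(length: float, spacing: float = 2.0) -> np.ndarray:
    """Straight centerline along +z; ``floor(length/spacing)+1`` points."""
    if length <= 0 or spacing <= 0:
        raise ParameterError("length and spacing must be positive")
    n = int(np.floor(length / spacing + 1e-9)) + 1
    pts = np.zeros((n, 3))
    pts[:, 2] = spacing * np.arange(n)
    return pts


def _arch_curve_dense(
    arch_height: float,
    arch_width: float,
    ascending_length: float,
    descending_length: float,
    n_dense: int = 20000,
) -> np.ndarray:
    """Densely sampled candy-cane curve in the x-z plane.

    Ascending limb up +z, then a half-ellipse with horizontal diameter
    ``arch_width`` and vertical diameter ``arch_height``, then the
    descending limb down -z.  C1-continuous at both junctions because the
    ellipse tangents at its ends are vertical.
    """
    a = arch_width / 2.0
    b = arch_height / 2.0
    n1 = max(2, int(n_dense * 0.2))
    n2 = max(2, int(n_dense * 0.5))
    n3 = max(2, n_dense - n1 - n2)

    t1 = np.linspace(0.0, ascending_length, n1, endpoint=False)
    seg1 = np.column_stack([np.zeros_like(t1), np.zeros_like(t1), t1])

    theta = np.linspace(0.0, np.pi, n2, endpoint=False)
    seg2 = np.column_stack(
        [a - a * np.cos(theta), np.zeros_like(theta), ascending_length + b * np.sin(theta)]
    )

    t3 = np.linspace(0.0, descending_length, n3)
    seg3 = np.column_stack(
        [np.full_like(t3, arch_width), np.zeros_like(t3), ascending_length - t3]
    )
    return np.vstack([seg1, seg2, seg3])


def resample_by_arc_length(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a dense polyline at equal arc-length intervals."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_out = int(np.floor(total / spacing + 1e-9)) + 1
    targets = spacing * np.arange(n_out)
    out = np.column_stack(
        [np.interp(targets, s, points[:, k]) for k in range(3)]
    )
    return out


def make_centerline(
    arch_height: float,
    arch_width: float,
    descending_length: float,
    spacing: float = 2.0,
    ascending_length: float = 40.0,
) -> np.ndarray:
    """Build a centerline with points spaced ``spacing`` mm apart (arc length).

    Returns an (n, 3) array in mm.  ``arch_height`` is the vertical diameter
    of the elliptical arch (so ``arch_height == arch_width`` yields a
    half-circular arch of arc length pi*arch_width/2).
    """
    if min(arch_height, arch_width, descending_length, ascending_length) <= 0:
        raise ParameterError("all centerline dimensions must be positive")
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    dense = _arch_curve_dense(arch_height, arch_width, ascending_length, descending_length)
    return resample_by_arc_length(dense, spacing)


def arch_segment_indices(
    spacing: float,
    ascending_length: float,
    arch_height: float,
    arch_width: float,
    n_points: int,
) -> tuple[int, int]:
    """Index range [start, end] of the arch segment of a generated centerline."""
    a, b = arch_width / 2.0, arch_height / 2.0
    theta = np.linspace(0.0, np.pi, 4000)
    d = np.hypot(a * np.sin(theta), b * np.cos(theta))
    arch_len = np.trapezoid(d, theta)
    start = int(np.ceil(ascending_length / spacing - 1e-9))
    end = int(np.floor((ascending_length + arch_len) / spacing + 1e-9))
    return start, min(end, n_points - 1)


def make_radius_profile(
    n: int,
    base_radius: float,
    stenosis_severity: float,
    stenosis_center: int,
    stenosis_width: int,
) -> np.ndarray:
    """Per-point lumen radius (mm) with a smooth Gaussian-bump narrowing.

    The minimum radius is ``base_radius * (1 - stenosis_severity)`` at
    ``stenosis_center``; ``stenosis_width`` is the characteristic full width
    in index units (the Gaussian sigma is width/2).
    """
    if not 0.0 <= stenosis_severity < 1.0:
        raise ParameterError(
            f"stenosis_severity must be in [0,1) (1 closes the lumen), got {stenosis_severity}"
        )
    if base_radius <= 0:
        raise ParameterError("base_radius must be positive")
    if not (0 <= stenosis_center < n and 0 < stenosis_width <= n):
        raise ParameterError("stenosis center/width must lie inside [0, n)")
    i = np.arange(n)
    sigma = stenosis_width / 2.0
    bump = np.exp(-0.5 * ((i - stenosis_center) / sigma) ** 2)
    return base_radius * (1.0 - stenosis_severity * bump)


def assign_flow_profile(
    inlet_flow: float, branches: list[BranchSpec], n: int
) -> np.ndarray:
    """Piecewise-constant per-point flow (m^3/s), diminished after each branch."""
    if inlet_flow <= 0:
        raise ParameterError("inlet_flow must be positive")
    total = sum(b.outflow_fraction for b in branches)
    if total >= 1.0:
        raise ParameterError("branch outflow fractions must sum to < 1")
    f = np.full(n, inlet_flow, dtype=float)
    for b in branches:
        f[b.attach_index + 1 :] -= inlet_flow * b.outflow_fraction
    return f


def measure_arch(points: np.ndarray, spacing: float | None = None) -> tuple[float, float]:
    """Measure (arch_height, arch_width) from a centerline, rigid-invariantly.

    Width is the maximum perpendicular distance of any point from the
    ascending axis (the line through the inlet along the inlet tangent);
    height is twice the rise of the apex above the arch shoulder, where the
    shoulder is the first point with non-negligible discrete curvature.
    """
    pts = np.asarray(points, dtype=float)
    t0 = pts[1] - pts[0]
    t0 = t0 / np.linalg.norm(t0)
    rel = pts - pts[0]
    proj = rel @ t0
    perp = rel - np.outer(proj, t0)
    width = float(np.linalg.norm(perp, axis=1).max())

    if spacing is None:
        spacing = float(np.linalg.norm(pts[1] - pts[0]))
    second = pts[2:] - 2 * pts[1:-1] + pts[:-2]
    curv = np.linalg.norm(second, axis=1) / spacing**2
    curved = np.nonzero(curv > _CURVATURE_EPS)[0]
    if curved.size == 0:
        return 0.0, width
    shoulder = proj[curved[0] + 1]
    apex = proj.max()
    height = 2.0 * float(apex - shoulder)
    return height, width


def classify_arch(
    geometry: AortaGeometry, threshold: float = 1.0, from_points: bool = True
) -> str:
    """Label an arch ``"gothic"`` or ``"non-gothic"``.

    Gothic means the measured height/width ratio strictly exceeds
    ``threshold`` (ties are non-gothic).  With ``from_points=False`` the
    generator's nominal arch dimensions are used instead of re-measuring.
    """
    if from_points:
        height, width = measure_arch(geometry.centerline_points, geometry.spacing)
    else:
        height, width = geometry.arch_height, geometry.arch_width
    if width <= 0:
        return "non-gothic"
    return "gothic" if height / width > threshold else "non-gothic"


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for the synthetic cohort.

    Defaults give total lengths below the 3D capacity (320 mm), stenosis
    severities spanning healthy to severe CoA, and combined arch branch
    outflow around 15--30% of cardiac output.
    """

    arch_width: tuple[float, float] = (40.0, 60.0)
    gothic_ratio: tuple[float, float] = (1.15, 1.6)
    non_gothic_ratio: tuple[float, float] = (0.6, 0.95)
    ascending_length: tuple[float, float] = (25.0, 40.0)
    descending_length: tuple[float, float] = (70.0, 120.0)
    base_radius: tuple[float, float] = (8.0, 12.0)
    severity: tuple[float, float] = (0.0, 0.6)
    stenosis_width_points: tuple[int, int] = (5, 10)
    branch_fraction: tuple[float, float] = (0.05, 0.10)
    inlet_flow_mls: tuple[float, float] = (200.0, 400.0)

    def validate(self):
        for name, rng in dataclasses.asdict(self).items():
            lo, hi = rng
            if hi < lo:
                raise ParameterError(f"empty range for {name}: {rng}")


def sample_cohort(
    n_cases: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    gothic_fraction: float = 0.5,
    spacing: float = 2.0,
) -> list[tuple[AortaGeometry, FlowBC]]:
    """Draw a reproducible synthetic cohort.

    The gothic/non-gothic split is stratified: exactly
    ``round(gothic_fraction * n_cases)`` cases get a gothic arch ratio.
    """
    if n_cases <= 0:
        raise ParameterError("n_cases must be positive")
    if not 0.0 <= gothic_fraction <= 1.0:
        raise ParameterError("gothic_fraction must be in [0,1]")
    ranges = ranges or CohortRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)

    n_gothic = int(round(gothic_fraction * n_cases))
    labels = np.array([True] * n_gothic + [False] * (n_cases - n_gothic))
    rng.shuffle(labels)

    def u(lo_hi):
        return rng.uniform(*lo_hi)

    cohort = []
    for k in range(n_cases):
        gothic = bool(labels[k])
        width = u(ranges.arch_width)
        ratio = u(ranges.gothic_ratio if gothic else ranges.non_gothic_ratio)
        height = ratio * width
        asc = u(ranges.ascending_length)
        desc = u(ranges.descending_length)
        pts = make_centerline(height, width, desc, spacing, ascending_length=asc)
        n = len(pts)
        a_start, a_end = arch_segment_indices(spacing, asc, height, width, n)

        # stenosis placed in the proximal descending aorta (juxtaductal CoA)
        desc_start = min(a_end + 2, n - 2)
        center = int(desc_start + rng.uniform(0.05, 0.45) * (n - 1 - desc_start))
        sev = u(ranges.severity)
        w_lo, w_hi = ranges.stenosis_width_points
        sten_w = int(rng.integers(w_lo, w_hi + 1))
        radius = make_radius_profile(n, u(ranges.base_radius), sev, center, sten_w)

        # three supra-aortic branches spread over the arch
        span = a_end - a_start
        attach = sorted(
            a_start + int(round(f * span)) for f in (0.25, 0.5, 0.75)
        )
        attach = list(dict.fromkeys(attach))  # dedupe for very short arches
        branches = [BranchSpec(i, u(ranges.branch_fraction)) for i in attach]

        geom = AortaGeometry(
            case_id=f"case_{seed:05d}_{k:04d}",
            centerline_points=pts,
            spacing=spacing,
            radius=radius,
            branches=branches,
            arch_height=height,
            arch_width=width,
            arch_start_index=a_start,
            arch_end_index=a_end,
        )
        bc = FlowBC(inlet_flow=mls_to_m3s(u(ranges.inlet_flow_mls)))
        cohort.append((geom, bc))
    return cohort
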