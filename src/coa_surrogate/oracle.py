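"""Reduced-order hemodynamic oracle.

Produces the eight centerline-aggregated output channels (pressure, WSS,
SFD, KE, average/maximum TKE, average/maximum velocity) for one case at
peak systole.  This is a quasi-steady one-dimensional energy-balance model
-- Bernoulli dynamic pressure referenced to the 120 mmHg inlet, cumulative
Poiseuille viscous loss, an irreversible Borda-Carnot expansion loss
downstream of the stenosis throat with partial pressure recovery, and an
optional curvature loss over gothic arches.  It is a deliberately simple
ground-truth generator for training and parameter-recovery studies; it is
not, and does not claim to be, a Navier-Stokes solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .geometry import INLET_PRESSURE_MMHG, AortaGeometry, FlowBC, assign_flow_profile
from .units import MMHG_PA, MM_M

__all__ = [
    "FluidProperties",
    "HemodynamicProfile",
    "OracleConfig",
    "solve_pressure",
    "compute_wss",
    "compute_aux_channels",
    "solve_case",
]


@dataclass(frozen=True)
class FluidProperties:
    """Blood constitutive constants (incompressible Newtonian)."""

    density: float = 1060.0  # kg/m^3
    viscosity: float = 3.5e-3  # Pa.s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity < 0:
            raise ParameterError("density must be > 0 and viscosity >= 0")


@dataclass(frozen=True)
class OracleConfig:
    """Tunable loss-model coefficients.

    ``bc_loss_coeff`` is the fraction of the ideal Borda-Carnot dissipation
    0.5*rho*(v_throat - v)^2 actually lost downstream of the throat (the
    remainder is recovered); ``gothic_loss_coeff`` scales the extra
    curvature loss accrued over the arch of tall narrow (gothic) arches;
    ``velocity_profile_factor`` is the ratio of peak to mean cross-section
    velocity (1 = plug flow, 2 = parabolic).
    """

    bc_loss_coeff: float = 0.7
    gothic_loss_coeff: float = 2.0
    gothic_threshold: float = 1.0
    velocity_profile_factor: float = 1.5
    tke_fraction: float = 0.05
    jet_decay_mm: float = 30.0
    noise_sd: float = 0.0
    noise_seed: int = 0


@dataclass
class HemodynamicProfile:
    """The eight per-centerline-point output channels of one case."""

    pressure: np.ndarray  # mmHg, relative static, pressure[0] == 120
    wss: np.ndarray  # Pa
    sfd: np.ndarray  # dimensionless
    ke: np.ndarray  # mJ/kg
    tke_avg: np.ndarray  # mJ/kg
    tke_max: np.ndarray  # mJ/kg
    v_avg: np.ndarray  # m/s
    v_max: np.ndarray  # m/s

    _CHANNELS = ("pressure", "wss", "sfd", "ke", "tke_avg", "tke_max", "v_avg", "v_max")

    def __post_init__(self):
        n = len(self.pressure)
        for name in self._CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ParameterError(f"channel {name} has wrong length")
        if abs(self.pressure[0] - INLET_PRESSURE_MMHG) > 0:
            raise ParameterError("inlet pressure must be exactly 120 mmHg")
        for name in ("wss", "ke", "tke_avg", "tke_max", "v_avg", "v_max"):
            if np.any(getattr(self, name) < 0):
                raise ParameterError(f"channel {name} must be non-negative")
        if np.any(self.v_max < self.v_avg - 1e-12):
            raise ParameterError("v_max must dominate v_avg point-wise")

    @property
    def n_points(self) -> int:
        return len(self.pressure)

    def as_matrix(self) -> np.ndarray:
        """Stack the channels into an (n, 8) array in the canonical order."""
        return np.column_stack([getattr(self, c) for c in self._CHANNELS])


def _mean_velocity(flow: np.ndarray, radius_mm: np.ndarray) -> np.ndarray:
    r_m = radius_mm * MM_M
    return flow / (np.pi * r_m**2)


def solve_pressure(
    geometry: AortaGeometry,
    bc: FlowBC,
    props: FluidProperties = FluidProperties(),
    config: OracleConfig = OracleConfig(),
) -> np.ndarray:
    """Per-point relative static pressure (mmHg), anchored at 120 at the inlet.

    p(x) = p_in - [ 0.5*rho*(v^2 - v_in^2)        (Bernoulli)
                  + cumulative 8*mu*f/(pi*r^4)    (Poiseuille)
                  + irreversible expansion loss   (Borda-Carnot, post-throat)
                  + gothic curvature loss ] / 133.322
    """
    if np.any(geometry.radius <= 0):
        raise ParameterError("lumen closure: all radii must be positive")
    n = geometry.n_points
    f = assign_flow_profile(bc.inlet_flow, geometry.branches, n)
    r_m = geometry.radius * MM_M
    h_m = geometry.spacing * MM_M
    v = _mean_velocity(f, geometry.radius)
    rho = props.density

    dyn = 0.5 * rho * (v**2 - v[0] ** 2)

    # trapezoidal cumulative Poiseuille pressure loss
    dpdx = 8.0 * props.viscosity * f / (np.pi * r_m**4)
    visc = np.concatenate([[0.0], np.cumsum(0.5 * (dpdx[1:] + dpdx[:-1]) * h_m)])

    # irreversible deceleration loss downstream of the throat
    i_t = geometry.stenosis_index
    bc_loss = np.zeros(n)
    decel = np.clip(v[i_t] - v[i_t:], 0.0, None)
    bc_loss[i_t:] = config.bc_loss_coeff * 0.5 * rho * decel**2

    # curvature loss over the arch of gothic shapes
    gothic_loss = np.zeros(n)
    if (
        geometry.arch_width > 0
        and geometry.arch_start_index is not None
        and geometry.arch_end_index is not None
    ):
        excess = max(
            geometry.arch_height / geometry.arch_width - config.gothic_threshold, 0.0
        )
        if excess > 0:
            a, b = geometry.arch_start_index, geometry.arch_end_index
            v_arch_sq = float(np.mean(v[a : b + 1] ** 2))
            total = config.gothic_loss_coeff * excess * 0.5 * rho * v_arch_sq
            ramp = np.clip(
                (np.arange(n) - a) / max(b - a, 1), 0.0, 1.0
            )
            gothic_loss = total * ramp

    p = INLET_PRESSURE_MMHG - (dyn + visc + bc_loss + gothic_loss) / MMHG_PA
    p[0] = INLET_PRESSURE_MMHG
    return p


def compute_wss(
    geometry: AortaGeometry,
    flow: np.ndarray,
    props: FluidProperties = FluidProperties(),
) -> np.ndarray:
    """Poiseuille wall shear stress tau = 4*mu*v/r (Pa) per centerline point."""
    if np.any(geometry.radius <= 0):
        raise ParameterError("all radii must be positive")
    v = _mean_velocity(np.asarray(flow, dtype=float), geometry.radius)
    r_m = geometry.radius * MM_M
    return 4.0 * props.viscosity * v / r_m


def compute_aux_channels(
    geometry: AortaGeometry,
    flow: np.ndarray,
    props: FluidProperties = FluidProperties(),
    config: OracleConfig = OracleConfig(),
) -> dict[str, np.ndarray]:
    """SFD, KE, TKE and velocity channels from the flow profile.

    KE is the specific kinetic energy of the mean flow, 500*v^2 mJ/kg.
    SFD and TKE are smooth, deterministic surrogates: both grow with the
    post-stenotic jet (excess of throat over local velocity, decaying
    exponentially with distance downstream) and SFD additionally with arch
    curvature (Dean-type secondary flow); both are zero in straight healthy
    segments.
    """
    n = geometry.n_points
    flow = np.asarray(flow, dtype=float)
    v_avg = _mean_velocity(flow, geometry.radius)
    v_max = config.velocity_profile_factor * v_avg
    ke = 500.0 * v_avg**2  # 0.5 v^2 J/kg -> mJ/kg

    i_t = geometry.stenosis_index
    s = geometry.arc_length()
    jet = np.zeros(n)
    downstream = np.arange(n) >= i_t
    decel = np.clip(v_avg[i_t] - v_avg, 0.0, None)
    decay = np.exp(-(s - s[i_t]) / config.jet_decay_mm)
    jet[downstream] = (decel * decay)[downstream]

    # discrete curvature (1/mm) for the Dean-type secondary-flow term
    pts = geometry.centerline_points
    curv = np.zeros(n)
    if n >= 3:
        second = pts[2:] - 2 * pts[1:-1] + pts[:-2]
        curv[1:-1] = np.linalg.norm(second, axis=1) / geometry.spacing**2

    sfd = 0.5 * np.sqrt(geometry.radius * curv) + 0.4 * jet / np.maximum(v_avg, 1e-12)
    tke_avg = config.tke_fraction * 1000.0 * 0.5 * jet**2  # mJ/kg
    tke_max = 2.0 * tke_avg

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.noise_seed)
        for arr in (sfd, tke_avg):
            arr += rng.normal(0.0, config.noise_sd, n)
            np.clip(arr, 0.0, None, out=arr)
        tke_max = np.maximum(tke_max, tke_avg)

    return {
        "sfd": sfd,
        "ke": ke,
        "tke_avg": tke_avg,
        "tke_max": tke_max,
        "v_avg": v_avg,
        "v_max": v_max,
    }


def solve_case(
    geometry: AortaGeometry,
    bc: FlowBC,
    props: FluidProperties = FluidProperties(),
    config: OracleConfig = OracleConfig(),
) -> HemodynamicProfile:
    """Run the full oracle for one case and return all eight channels."""
    n = geometry.n_points
    flow = assign_flow_profile(bc.inlet_flow, geometry.branches, n)
    pressure = solve_pressure(geometry, bc, props, config)
    wss = compute_wss(geometry, flow, props)
    aux = compute_aux_channels(geometry, flow, props, config)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.noise_seed + 1)
        pressure = pressure + rng.normal(0.0, config.noise_sd, n)
        pressure[0] = INLET_PRESSURE_MMHG
        wss = np.clip(wss + rng.normal(0.0, config.noise_sd, n), 0.0, None)
    return HemodynamicProfile(pressure=pressure, wss=wss, **aux)
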