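"""Centerline-aggregated (1D) training records.

Each case becomes a zero-padded (178 x 7) input table -- radius, radius
gradient, the three case-local centerline coordinates, flow and mean
cross-section velocity -- and a (178 x 8) output table holding the eight
hemodynamic channels, with the WSS channel smoothed by a 12-sample moving
average.  Padded rows beyond ``valid_length`` are exactly zero, and the
valid length is stored explicitly so genuinely zero-valued outputs are
never confused with padding.

Feature-table units: radius and coordinates in mm, flow in ml/s, velocity
in m/s, pressure in mmHg, WSS in Pa, KE/TKE in mJ/kg (the networks train
on unscaled values, so units fix the feature magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, ParameterError
from .geometry import AortaGeometry, FlowBC
from .oracle import HemodynamicProfile
from .units import MM_M, m3s_to_mls

DEFAULT_N_PAD = 178
"""Padded sequence length: the longest admissible aorta is 178 points x 2 mm = 356 mm."""

INPUT_FEATURES = ("radius", "radius_gradient", "x", "y", "z", "flow", "v_avg")
OUTPUT_FEATURES = ("pressure", "wss", "sfd", "ke", "tke_avg", "tke_max", "v_avg", "v_max")


@dataclass(frozen=True)
class SmoothingSpec:
    """Moving-average window (in rings) for the WSS channel."""

    window: int = 12

    def __post_init__(self):
        if self.window < 1:
            raise ParameterError("smoothing window must be >= 1")


@dataclass
class Case1D:
    """One padded 1D training record."""

    case_id: str
    inputs: np.ndarray  # (N_pad, 7)
    outputs: np.ndarray  # (N_pad, 8)
    valid_length: int
    n_pad: int = DEFAULT_N_PAD

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.inputs.shape != (self.n_pad, len(INPUT_FEATURES)):
            raise ParameterError(f"inputs must be ({self.n_pad}, 7)")
        if self.outputs.shape != (self.n_pad, len(OUTPUT_FEATURES)):
            raise ParameterError(f"outputs must be ({self.n_pad}, 8)")
        if not 10 <= self.valid_length <= self.n_pad:
            raise ParameterError("valid_length must be in [10, n_pad]")
        if np.any(self.inputs[self.valid_length :]) or np.any(
            self.outputs[self.valid_length :]
        ):
            raise ParameterError("padded rows must be exactly zero")

    @property
    def mask(self) -> np.ndarray:
        """Boolean (N_pad,) validity mask."""
        m = np.zeros(self.n_pad, dtype=bool)
        m[: self.valid_length] = True
        return m

    def unpad(self) -> tuple[np.ndarray, np.ndarray]:
        """Recover the unpadded per-point input/output tables."""
        return (
            self.inputs[: self.valid_length].copy(),
            self.outputs[: self.valid_length].copy(),
        )


def radius_gradient(r: np.ndarray, h: float) -> np.ndarray:
    """Second-order radius gradient: central differences in the interior,
    one-sided first-order differences at the two endpoints."""
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or len(r) < 2:
        raise ParameterError("radius profile must be 1D with length >= 2")
    if h <= 0:
        raise ParameterError("spacing must be positive")
    g = np.empty_like(r)
    g[1:-1] = (r[2:] - r[:-2]) / (2.0 * h)
    g[0] = (r[1] - r[0]) / h
    g[-1] = (r[-1] - r[-2]) / h
    return g


def mean_velocity(f: np.ndarray, r: np.ndarray) -> np.ndarray:
    """v = f / (pi r^2) element-wise; ``f`` in m^3/s, ``r`` in metres."""
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("lumen radius must be positive")
    return f / (np.pi * r**2)


def smooth_wss(wss: np.ndarray, spec: SmoothingSpec = SmoothingSpec()) -> np.ndarray:
    """Centered moving average over ``spec.window`` samples.

    At the sequence ends the window shrinks symmetrically so the filter
    stays centered and unbiased for constant inputs.  An even window is
    taken as half-width ``window // 2`` on each side with the current
    sample included.
    """
    w = np.asarray(wss, dtype=float)
    half = spec.window // 2
    if half == 0:
        return w.copy()
    n = len(w)
    out = np.empty_like(w)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = w[i - k : i + k + 1].mean()
    return out


def build_case_1d(
    geometry: AortaGeometry,
    bc: FlowBC,
    profile: HemodynamicProfile,
    n_pad: int = DEFAULT_N_PAD,
    smoothing: SmoothingSpec = SmoothingSpec(),
) -> Case1D:
    """Assemble the padded 1D record for one solved case."""
    n = geometry.n_points
    if n > n_pad:
        raise CapacityError(
            f"case {geometry.case_id} has {n} points, exceeding the padded "
            f"capacity of {n_pad} ({n_pad * geometry.spacing:.0f} mm)"
        )
    if profile.n_points != n:
        raise ParameterError("profile length does not match geometry")

    from .geometry import assign_flow_profile  # local to avoid cycle at import

    flow = assign_flow_profile(bc.inlet_flow, geometry.branches, n)
    grad = radius_gradient(geometry.radius, geometry.spacing)
    v = mean_velocity(flow, geometry.radius * MM_M)

    inputs = np.zeros((n_pad, len(INPUT_FEATURES)))
    outputs = np.zeros((n_pad, len(OUTPUT_FEATURES)))
    inputs[:n, 0] = geometry.radius
    inputs[:n, 1] = grad
    inputs[:n, 2:5] = geometry.centerline_points
    inputs[:n, 5] = m3s_to_mls(flow)
    inputs[:n, 6] = v

    out = profile.as_matrix()
    out = out.copy()
    out[:, 1] = smooth_wss(out[:, 1], smoothing)
    outputs[:n] = out

    return Case1D(
        case_id=geometry.case_id,
        inputs=inputs,
        outputs=outputs,
        valid_length=n,
        n_pad=n_pad,
    )


def stack_cases(cases: list[Case1D]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack records into (C, N_pad, 7), (C, N_pad, 8) arrays + valid lengths."""
    X = np.stack([c.inputs for c in cases])
    Y = np.stack([c.outputs for c in cases])
    lengths = np.array([c.valid_length for c in cases], dtype=np.int64)
    return X, Y, lengths


def lengths_to_mask(lengths: np.ndarray, n_pad: int) -> np.ndarray:
    """Boolean (C, N_pad) mask from per-case valid lengths."""
    return np.arange(n_pad)[None, :] < np.asarray(lengths)[:, None]
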