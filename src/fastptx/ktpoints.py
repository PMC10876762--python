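"""3-kT-point benchmark designer.

A kT-point pulse visits a small set of excitation k-space locations with
rectangular RF sub-pulses, hopping between locations with gradient blips.
Channel weights per point are found by magnitude-least-squares (MLS) B1
shimming via the variable-exchange method; the first two k-space locations
are picked by random search, the third sits at the k-space origin (so the
pulse ends on-center).  This is the classic sparse alternative that the free
joint waveform optimization is benchmarked against.

k-space positions are in rad/m, matching the ``k . r`` phase of the
spatial-domain system matrix (``k = -gamma * int_t^T g``).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fieldmaps import FieldMapSet
from .cost import Limits
from .optimize import gradient_blip
from .pulse import PulseWaveform
from .sim import GAMMA

__all__ = [
    "KtPointSpec",
    "variable_exchange_mls",
    "kt_system_matrix",
    "random_kt_search",
    "assemble_kt_pulse",
]


@dataclasses.dataclass
class KtPointSpec:
    """Three k-space positions [rad/m] and the sub-pulse/gap timing.

    The third position must be the k-space origin.  Total duration is
    ``3 * subpulse_duration + 2 * gap_duration``.
    """

    positions: np.ndarray
    subpulse_duration: float = 130e-6
    gap_duration: float = 60e-6
    raster: float = 10e-6

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (3, 3):
            raise ValueError(f"need 3 k-space positions (3x3), got {self.positions.shape}")
        if np.any(self.positions[2] != 0.0):
            raise ValueError("the third kT point must sit at the k-space origin")
        for name in ("subpulse_duration", "gap_duration", "raster"):
            n = getattr(self, name) / self.raster
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(f"{name} is not a multiple of the raster")

    @property
    def n_points(self) -> int:
        return 3

    @property
    def total_duration(self) -> float:
        return 3 * self.subpulse_duration + 2 * self.gap_duration


def variable_exchange_mls(a: np.ndarray, target_mag: np.ndarray, n_iter: int = 20):
    """Magnitude-least-squares shim weights by variable exchange.

    Alternates between the least-squares solve ``b = pinv(A) (t * exp(i phi))``
    and the phase update ``phi = arg(A b)``, starting from phase 0; this is
    unregularized alternating minimization of ``|| |A b| - t ||``.

    Returns (weights, residuals) where residuals[k] is the magnitude residual
    norm after iteration k (non-increasing).
    """
    a = np.asarray(a, dtype=np.complex128)
    target_mag = np.asarray(target_mag, dtype=np.float64).ravel()
    if target_mag.size == 0:
        raise ValueError("empty target")
    if a.shape[0] != target_mag.size:
        raise ValueError(f"A has {a.shape[0]} rows but target has {target_mag.size}")
    pinv = np.linalg.pinv(a)
    phase = np.zeros(target_mag.size)
    residuals = []
    b = pinv @ target_mag
    for _ in range(n_iter):
        z = a @ b
        residuals.append(float(np.linalg.norm(np.abs(z) - target_mag)))
        phase = np.angle(z)
        b = pinv @ (target_mag * np.exp(1j * phase))
    z = a @ b
    residuals.append(float(np.linalg.norm(np.abs(z) - target_mag)))
    return b, residuals


def kt_system_matrix(maps: FieldMapSet, spec: KtPointSpec) -> np.ndarray:
    """Coarse STA matrix at sub-pulse granularity.

    One effective sample per (point, channel): element (voxel; point p,
    channel c) = i gamma tau b1_c(r) 1e-9 exp(i [k_p.r + 2 pi b0(r)(t_p - T)])
    with t_p the sub-pulse center.  Unknown ordering is point-major
    (weights.reshape(-1) for weights of shape (3, n_channels)).
    """
    coords = maps.coords_masked()
    b0 = maps.b0_masked()
    b1 = maps.b1_masked() * 1e-9  # (nv, nc)
    tau = spec.subpulse_duration
    total = spec.total_duration
    nv, nc = b1.shape
    cols = []
    for p in range(3):
        t_center = p * (tau + spec.gap_duration) + tau / 2.0
        ph = coords @ spec.positions[p] + 2.0 * np.pi * b0 * (t_center - total)
        phase_factor = np.exp(1j * ph)  # (nv,)
        cols.append(1j * GAMMA * tau * b1 * phase_factor[:, None])  # (nv, nc)
    return np.concatenate(cols, axis=1)


def random_kt_search(
    maps: FieldMapSet,
    n_candidates: int = 5000,
    k_max: float = 14.0,
    seed: int = 0,
    fa: float = 10.0,
    n_iter_mls: int = 20,
) -> KtPointSpec:
    """Pick the best pair of k-space positions for points 1-2 by random search.

    Draws ``n_candidates`` pairs uniformly from the cube |k_{x,y,z}| <= k_max
    [rad/m] (point 3 stays at the origin), scores each by the MLS residual
    after variable exchange, and returns the best-scoring spec.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    target = np.full(maps.n_masked, np.radians(fa))
    best = None
    best_res = np.inf
    for _ in range(n_candidates):
        pts = np.zeros((3, 3))
        pts[:2] = rng.uniform(-k_max, k_max, size=(2, 3))
        spec = KtPointSpec(positions=pts)
        a = kt_system_matrix(maps, spec)
        _, residuals = variable_exchange_mls(a, target, n_iter=n_iter_mls)
        if residuals[-1] < best_res:
            best_res = residuals[-1]
            best = spec
    return best


def assemble_kt_pulse(
    spec: KtPointSpec,
    weights: np.ndarray,
    limits: Limits | None = None,
) -> PulseWaveform:
    """Build the playable waveform: rectangular sub-pulses + gradient blips.

    ``weights`` has shape (3, n_channels) [V].  During each gap a symmetric
    blip per axis moves k by (k_next - k_current); its area is
    (k_next - k_current) / gamma, respecting the gradient and slew limits
    (ValueError if infeasible).  RF is zero during the blips.
    """
    limits = limits or Limits()
    weights = np.asarray(weights, dtype=np.complex128)
    if weights.ndim != 2 or weights.shape[0] != 3:
        raise ValueError(f"weights must have shape (3, n_channels), got {weights.shape}")
    nc = weights.shape[1]
    dt = spec.raster
    n_sub = int(round(spec.subpulse_duration / dt))
    n_gap = int(round(spec.gap_duration / dt))
    nt = 3 * n_sub + 2 * n_gap

    rf = np.zeros((nc, nt), dtype=np.complex128)
    grad = np.zeros((3, nt))
    for p in range(3):
        i0 = p * (n_sub + n_gap)
        rf[:, i0:i0 + n_sub] = weights[p][:, None]
        if p < 2:
            dk = spec.positions[p + 1] - spec.positions[p]  # rad/m
            for ax in range(3):
                area = dk[ax] / GAMMA  # T*s/m
                grad[ax, i0 + n_sub:i0 + n_sub + n_gap] = gradient_blip(
                    area, n_gap, dt, limits.g_limit, limits.s_limit
                )
    return PulseWaveform(rf=rf, grad=grad, raster=dt)
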