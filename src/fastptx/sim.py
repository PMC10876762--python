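"""Forward models: hard-pulse Bloch simulation and the small-tip-angle method.

Both models consume a :class:`~fastptx.pulse.PulseWaveform` and a
:class:`~fastptx.fieldmaps.FieldMapSet` and are restricted to masked voxels.

Bloch model
    Per raster step the effective field at a voxel is
    ``B = (Re sum_c b1_c rf_c, Im sum_c b1_c rf_c, g.r + 2 pi b0 / gamma)``
    and the magnetization is advanced by the exact axis-angle rotation
    ``dM/dt = gamma M x B`` (norm-preserving by construction), with optional
    T1/T2 relaxation interleaved as a separable decay/regrowth step.

Small-tip-angle (STA) model
    Linearizes the Bloch equations around equilibrium: the transverse
    magnetization is ``m = A b`` with the spatial-domain system matrix
    ``A[(r),(c,t)] = i gamma b1_c(r) dt exp(i [k(t).r + 2 pi b0(r) (t - T)])``
    and the excitation k-space trajectory ``k(t) = -gamma int_t^T g(s) ds``
    (phase referenced to the pulse end, so k(T) = 0).

Sign convention (documented; the models share it): positive ``B_z`` - from a
gradient or positive off-resonance - precesses ``M_xy`` clockwise, i.e. the
accrued phase is negative, consistent with ``dM/dt = gamma M x B`` and with
the ``exp(i 2 pi b0 (t - T))`` factor of the system matrix.

The module-level kernels (``*_core``) accept plain float arrays or
:mod:`fastptx.autodiff` Tensors for the RF (real/imag parts) and gradient
samples, so every simulated quantity is differentiable with respect to the
waveforms.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .fieldmaps import FieldMapSet
from .pulse import PulseWaveform

__all__ = [
    "GAMMA",
    "GAMMA_HZ",
    "RelaxationSpec",
    "SimResult",
    "bloch_simulate",
    "sta_simulate",
    "sta_system_matrix",
    "fa_phase_from_state",
    "nrmse",
]

#: proton gyromagnetic ratio [rad/s/T]
GAMMA = 267.522e6
#: gamma / 2 pi [Hz/T]
GAMMA_HZ = GAMMA / (2.0 * np.pi)

_TINY = 1e-60  # guards sqrt(0) in norms; negligible against any physical field


@dataclasses.dataclass
class RelaxationSpec:
    """T1/T2 relaxation [s] and equilibrium magnetization (np.inf disables)."""

    t1: float = np.inf
    t2: float = np.inf
    m0: float = 1.0

    def __post_init__(self):
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError("t1 and t2 must be positive (np.inf to disable)")


@dataclasses.dataclass
class SimResult:
    """Per-masked-voxel magnetization and derived maps.

    ``mxy`` is complex (M0-normalized M_x + i M_y), ``mz`` longitudinal,
    ``fa`` and ``phase`` in degrees.
    """

    mxy: np.ndarray
    mz: np.ndarray
    fa: np.ndarray
    phase: np.ndarray


# ----------------------------------------------------------------------
# shared helpers
# ----------------------------------------------------------------------

def _rf_fields(maps: FieldMapSet, rf_re, rf_im):
    """Transverse field components [T] per masked voxel and sample.

    Returns (bx, by), each of shape (n_masked, n_samples), from the complex
    product of the nT/V sensitivities with the RF voltages.
    """
    b1 = maps.b1_masked() * 1e-9  # nT/V -> T/V
    b1r = np.ascontiguousarray(b1.real)
    b1i = np.ascontiguousarray(b1.imag)
    bx = b1r @ rf_re - b1i @ rf_im
    by = b1r @ rf_im + b1i @ rf_re
    return bx, by


def bloch_core(rf_re, rf_im, grad, maps: FieldMapSet, raster: float,
               relax: RelaxationSpec | None = None, initial=None):
    """Advance magnetization through the pulse; backend-generic.

    ``initial`` is an (n_masked, 3) float array (default equilibrium
    (0, 0, m0)).  Returns (mx, my, mz) arrays/Tensors of shape (n_masked,).
    """
    dt = float(raster)
    coords = maps.coords_masked()  # (nv, 3)
    b0 = maps.b0_masked()
    nv = coords.shape[0]
    m0 = 1.0 if relax is None else relax.m0

    bx_all, by_all = _rf_fields(maps, rf_re, rf_im)
    bz_grad = coords @ grad  # (nv, nt) [T]
    bz_off = (2.0 * np.pi / GAMMA) * b0  # (nv,) [T]

    if initial is None:
        mx = np.zeros(nv)
        my = np.zeros(nv)
        mz = np.full(nv, m0)
    else:
        initial = np.asarray(initial, dtype=np.float64)
        if initial.shape != (nv, 3):
            raise ValueError(f"initial magnetization must have shape ({nv}, 3)")
        mx, my, mz = initial[:, 0].copy(), initial[:, 1].copy(), initial[:, 2].copy()

    do_relax = relax is not None and (np.isfinite(relax.t1) or np.isfinite(relax.t2))
    if do_relax:
        e1 = float(np.exp(-dt / relax.t1))
        e2 = float(np.exp(-dt / relax.t2))

    nt = bz_grad.shape[1] if not isinstance(bz_grad, ad.Tensor) else bz_grad.data.shape[1]
    for t in range(nt):
        bx = bx_all[:, t]
        by = by_all[:, t]
        bz = bz_grad[:, t] + bz_off
        bn = ad.sqrt(bx * bx + by * by + bz * bz + _TINY)
        alpha = (-GAMMA * dt) * bn  # rotation angle about B-hat (right-handed)
        ca = ad.cos(alpha)
        sa = ad.sin(alpha)
        nx, ny, nz = bx / bn, by / bn, bz / bn
        ndot = nx * mx + ny * my + nz * mz
        cx = ny * mz - nz * my
        cy = nz * mx - nx * mz
        cz = nx * my - ny * mx
        k = ndot * (1.0 - ca)
        mx = mx * ca + cx * sa + nx * k
        my = my * ca + cy * sa + ny * k
        mz = mz * ca + cz * sa + nz * k
        if do_relax:
            mx = mx * e2
            my = my * e2
            mz = mz * e1 + relax.m0 * (1.0 - e1)
    return mx, my, mz


def bloch_simulate(pulse: PulseWaveform, maps: FieldMapSet,
                   relax: RelaxationSpec | None = None,
                   initial="equilibrium") -> SimResult:
    """Full Bloch simulation of `pulse` on the masked voxels of `maps`.

    ``initial`` is either ``"equilibrium"`` or an (n_masked, 3) array of
    magnetization vectors.  Returns the final state with FA/phase maps
    (FA = atan2(|mxy|, mz) in degrees).
    """
    if pulse.n_samples == 0:
        raise ValueError("zero-length pulse")
    if pulse.n_channels != maps.n_channels:
        raise ValueError(
            f"pulse has {pulse.n_channels} channels, maps have {maps.n_channels}"
        )
    init = None if (isinstance(initial, str) and initial == "equilibrium") else initial
    mx, my, mz = bloch_core(
        np.ascontiguousarray(pulse.rf.real),
        np.ascontiguousarray(pulse.rf.imag),
        pulse.grad, maps, pulse.raster, relax=relax, initial=init,
    )
    mxy = mx + 1j * my
    fa, phase = fa_phase_from_state(mxy, mz)
    return SimResult(mxy=mxy, mz=mz, fa=fa, phase=phase)


# ----------------------------------------------------------------------
# small-tip-angle model
# ----------------------------------------------------------------------

def _sta_phases(maps: FieldMapSet, grad, raster: float, nt: int):
    """Spatial phase [rad] per masked voxel and sample; backend-generic in grad.

    phase(r, t) = k(t).r + 2 pi b0(r) (t_t - T) with
    k(t) = -gamma dt (S - C_t)  (C inclusive cumsum, S total), so k(T) = 0.
    """
    dt = float(raster)
    coords = maps.coords_masked()
    b0 = maps.b0_masked()
    csum = ad.cumsum(grad, axis=1)  # (3, nt)
    total = csum[:, nt - 1 : nt]  # (3, 1)
    k = (GAMMA * dt) * (csum - total)  # = -gamma dt (S - C) [rad/m]
    phase_g = coords @ k  # (nv, nt)
    t_rel = dt * (np.arange(nt) + 1.0 - nt)  # t_t - T, last sample 0
    phase_b0 = 2.0 * np.pi * b0[:, None] * t_rel[None, :]
    return phase_g + phase_b0


def sta_core(rf_re, rf_im, grad, maps: FieldMapSet, raster: float):
    """Transverse magnetization (re, im) under the STA; backend-generic."""
    dt = float(raster)
    nt = rf_re.shape[1] if not isinstance(rf_re, ad.Tensor) else rf_re.data.shape[1]
    ph = _sta_phases(maps, grad, raster, nt)
    cph = ad.cos(ph)
    sph = ad.sin(ph)
    b1 = maps.b1_masked()  # nT/V
    b1r = np.ascontiguousarray(b1.real)
    b1i = np.ascontiguousarray(b1.imag)
    wre = b1r @ rf_re - b1i @ rf_im  # (nv, nt) [nT]
    wim = b1r @ rf_im + b1i @ rf_re
    scale = GAMMA * dt * 1e-9
    # i * e^{i ph} * w summed over samples
    mxy_re = ad.asum(cph * wim + sph * wre, axis=1) * (-scale)
    mxy_im = ad.asum(cph * wre - sph * wim, axis=1) * scale
    return mxy_re, mxy_im


def sta_simulate(pulse: PulseWaveform, maps: FieldMapSet) -> SimResult:
    """STA simulation: mxy = A b, mz reported as M0 = 1, FA = |mxy| in degrees."""
    if pulse.n_samples == 0:
        raise ValueError("zero-length pulse")
    if pulse.n_channels != maps.n_channels:
        raise ValueError(
            f"pulse has {pulse.n_channels} channels, maps have {maps.n_channels}"
        )
    re, im = sta_core(
        np.ascontiguousarray(pulse.rf.real),
        np.ascontiguousarray(pulse.rf.imag),
        pulse.grad, maps, pulse.raster,
    )
    mxy = re + 1j * im
    fa = np.abs(mxy) * (180.0 / np.pi)
    phase = np.degrees(np.arctan2(im, re))
    phase = np.where(np.abs(mxy) == 0.0, 0.0, phase)
    return SimResult(mxy=mxy, mz=np.ones_like(re), fa=fa, phase=phase)


def sta_system_matrix(maps: FieldMapSet, grad: np.ndarray, raster: float) -> np.ndarray:
    """Explicit spatial-domain system matrix A.

    Shape (n_masked, n_channels * n_samples); the unknown vector is
    ``pulse.rf.reshape(-1)`` (channel-major, C order), so
    ``mxy = A @ rf.reshape(-1)``.  Rebuilt from the current gradients on
    every call.
    """
    grad = np.asarray(grad, dtype=np.float64)
    if grad.ndim != 2 or grad.shape[0] != 3:
        raise ValueError(f"grad must have shape (3, n_samples), got {grad.shape}")
    nt = grad.shape[1]
    dt = float(raster)
    ph = _sta_phases(maps, grad, raster, nt)  # (nv, nt)
    phase_factor = np.exp(1j * ph)
    b1 = maps.b1_masked() * 1e-9  # (nv, nc) [T/V]
    # A[v, c*nt + t] = i gamma dt b1[v, c] e^{i ph[v, t]}
    a = 1j * GAMMA * dt * b1[:, :, None] * phase_factor[:, None, :]
    return a.reshape(a.shape[0], -1)


# ----------------------------------------------------------------------
# derived maps and metrics
# ----------------------------------------------------------------------

def fa_phase_from_state(mxy: np.ndarray, mz: np.ndarray):
    """Flip angle and phase [deg] from a Bloch state: fa = atan2(|mxy|, mz)."""
    mxy = np.asarray(mxy)
    amp = np.abs(mxy)
    fa = np.degrees(np.arctan2(amp, np.asarray(mz, dtype=np.float64)))
    phase = np.where(amp == 0.0, 0.0, np.degrees(np.angle(mxy)))
    return fa, phase


def nrmse(fa: np.ndarray, target_fa, mask: np.ndarray | None = None) -> float:
    """Normalized RMS flip-angle error in percent.

    sqrt(mean over (masked) voxels of (fa - target)^2) / mean(target) * 100.
    ``fa`` and ``target_fa`` may be full grids (then ``mask`` selects voxels)
    or already-masked flat arrays; a scalar target is broadcast.
    """
    fa = np.asarray(fa, dtype=np.float64)
    target = np.broadcast_to(np.asarray(target_fa, dtype=np.float64), fa.shape)
    if mask is not None:
        fa = fa[mask]
        target = target[mask]
    denom = target.mean()
    if denom == 0:
        raise ValueError("mean target flip angle is zero; NRMSE undefined")
    return float(np.sqrt(np.mean((fa - target) ** 2)) / denom * 100.0)
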