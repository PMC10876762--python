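"""Synthetic phantoms: field maps, SAR matrices and reference pulses.

Everything here is generated, deterministic under a seed, and physically
plausible rather than electromagnetically simulated: the designers only need
smooth, channel-distinct complex sensitivities over a head-like mask, a smooth
off-resonance field, and Hermitian positive-semidefinite SAR matrices of a
realistic scale.

The transmit array is modeled as ``n_channels`` loop elements on a ring
around an ellipsoidal "brain".  Each element's magnitude falls off with a
Gaussian of the distance to the element; its phase combines a propagation-like
term (linear in that distance) with a small smooth per-channel polynomial.
The per-channel phases are referenced so that the CP (circularly polarized)
mode interferes constructively at the grid center, as a birdcage-like drive
does in a real head coil, with partial destructive interference toward the
periphery - the classic ultra-high-field center-brightening pattern that the
pulse designers exist to fight.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .fieldmaps import FieldMapSet, build_coords
from .pulse import PulseWaveform
from .sar import VOPSet

__all__ = ["PhantomSpec", "synth_fieldmaps", "synth_vops", "cp_mode_pulse"]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the synthetic head phantom.

    b0_range is the peak magnitude [Hz] of the smooth off-resonance field;
    cp_center_b1 sets |CP-mode B1+| at the grid center [nT/V] (head-coil
    scale at ultra-high field is a few tens of nT/V).
    """

    n_channels: int = 16
    grid_shape: tuple = (32, 32, 32)
    resolution: float = 0.007
    b0_range: float = 300.0
    seed: int = 0
    cp_center_b1: float = 30.0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.b0_range < 0:
            raise ValueError("b0_range must be >= 0")
        if any(n < 2 for n in self.grid_shape):
            raise ValueError(f"degenerate grid {self.grid_shape}: need >= 2 voxels per axis")


def synth_fieldmaps(spec: PhantomSpec) -> FieldMapSet:
    """Generate a deterministic synthetic :class:`FieldMapSet` from `spec`."""
    rng = np.random.default_rng(spec.seed)
    nc = spec.n_channels
    coords = build_coords(spec.grid_shape, spec.resolution)
    half_extent = np.array([n * spec.resolution / 2.0 for n in spec.grid_shape])

    # ellipsoidal brain mask, semi-axes ~45% of the grid extent per axis
    semi = 0.9 * half_extent
    u = coords / semi
    mask = np.sum(u * u, axis=-1) <= 1.0

    # Ring of loop elements in the xy-plane, just outside the mask, with a
    # little per-element geometry jitter (no two real coil elements match).
    theta = 2.0 * np.pi * np.arange(nc) / nc
    r_coil = 1.15 * half_extent[:2].min() * (1.0 + 0.05 * rng.normal(size=nc))

    # The falloff and propagation-phase rates set the severity of the CP-mode
    # interference pattern: these values reproduce the strong center-bright
    # inhomogeneity of a head coil at ultra-high field (CP flip-angle NRMSE
    # around 35-40% against a uniform target).  The transverse falloff is
    # sharp (loop locality) while the longitudinal falloff is mild (elements
    # cover the head in z), and each channel carries its own smooth low-order
    # phase ripple - that per-channel diversity is what makes the phantom
    # homogenizable by pTx shimming, as real arrays are.  Ripple phases are
    # referenced to zero at the grid center so the CP mode stays exactly
    # coherent (and hence strictly positive) there.
    hem = float(half_extent.min())
    sigma_t = 0.5 * hem  # transverse magnitude falloff [m]
    sigma_z = 1.5 * hem  # longitudinal magnitude falloff [m]
    beta = 6.0 / hem  # propagation phase rate [rad/m]

    center = (np.array(spec.grid_shape) - 1) // 2
    b1 = np.empty((nc, *spec.grid_shape), dtype=np.complex128)
    for c in range(nc):
        px, py = r_coil[c] * np.cos(theta[c]), r_coil[c] * np.sin(theta[c])
        dt2 = (coords[..., 0] - px) ** 2 + (coords[..., 1] - py) ** 2
        d3 = np.sqrt(dt2 + coords[..., 2] ** 2)
        d0 = d3[tuple(center)]
        mag = np.exp(-dt2 / (2.0 * sigma_t**2)) * np.exp(
            -(coords[..., 2] ** 2) / (2.0 * sigma_z**2)
        )
        q = rng.normal(scale=0.8, size=6)
        ripple = (
            q[0] * u[..., 0] + q[1] * u[..., 1] + q[2] * u[..., 2]
            + q[3] * u[..., 0] * u[..., 1] + q[4] * u[..., 1] * u[..., 2]
            + q[5] * u[..., 0] ** 2
        )
        ripple = ripple - ripple[tuple(center)]
        phase = -theta[c] - beta * (d3 - d0) + ripple
        b1[c] = mag * np.exp(1j * phase)

    # scale so the CP-mode combination hits cp_center_b1 [nT/V] at the center
    cp_weights = np.exp(1j * theta)
    cp_center = abs(np.sum(cp_weights * b1[(slice(None), *center)]))
    b1 *= spec.cp_center_b1 / cp_center

    # smooth low-order polynomial off-resonance, normalized to +-b0_range
    p = rng.normal(size=9)
    poly = (
        p[0] * u[..., 0] + p[1] * u[..., 1] + p[2] * u[..., 2]
        + p[3] * u[..., 0] * u[..., 1] + p[4] * u[..., 0] * u[..., 2]
        + p[5] * u[..., 1] * u[..., 2]
        + p[6] * u[..., 0] ** 2 + p[7] * u[..., 1] ** 2 + p[8] * u[..., 2] ** 2
    )
    peak = np.abs(poly[mask]).max()
    b0 = np.zeros(spec.grid_shape) if peak == 0 else poly * (spec.b0_range / peak)
    b0 = np.clip(b0, -spec.b0_range, spec.b0_range)

    return FieldMapSet(b1=b1, b0=b0, mask=mask, resolution=spec.resolution)


def synth_vops(
    n_vops: int,
    n_channels: int,
    seed: int = 0,
    scale: float = 2e-3,
) -> VOPSet:
    """Random Hermitian PSD SAR matrices [W/kg per V^2].

    Each matrix is G G^H for a random complex G, rescaled so its largest
    eigenvalue equals `scale`.  The default scale is anchored to measured
    head-coil behavior: a CP-mode rectangular pulse scaled to a 10 degree
    mean flip angle on the synthetic maps deposits close to 1 W/kg of local
    SAR at a typical gradient-echo duty cycle (520 us pulse, 19.7 ms TR).
    """
    if n_vops < 1:
        raise ValueError("n_vops must be >= 1")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    mats = np.empty((n_vops, n_channels, n_channels), dtype=np.complex128)
    for v in range(n_vops):
        g = rng.normal(size=(n_channels, n_channels)) + 1j * rng.normal(
            size=(n_channels, n_channels)
        )
        m = g @ g.conj().T
        m = 0.5 * (m + m.conj().T)
        lam = np.linalg.eigvalsh(m).max()
        mats[v] = m * (scale / lam)
    return VOPSet(matrices=mats)


def cp_mode_pulse(
    n_channels: int, voltage: float, duration: float, raster: float
) -> PulseWaveform:
    """Rectangular CP-mode pulse: equal magnitudes, phase 2*pi*c/N per channel.

    The phase increment matches the ring azimuth of :func:`synth_fieldmaps`,
    so this is the birdcage-like quadrature drive on the synthetic coil.
    Gradients are zero.
    """
    n = duration / raster
    n_samples = int(round(n))
    if n_samples < 1 or abs(n - n_samples) > 1e-9 * max(1.0, n):
        raise ValueError(
            f"duration {duration} s is not a positive multiple of the raster {raster} s"
        )
    phases = np.exp(2j * np.pi * np.arange(n_channels) / n_channels)
    rf = voltage * np.repeat(phases[:, None], n_samples, axis=1)
    return PulseWaveform(rf=rf, grad=np.zeros((3, n_samples)), raster=raster)
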