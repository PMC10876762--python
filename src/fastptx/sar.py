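"""Local SAR prediction from a Virtual Observation Points (VOP) model.

A VOP file compresses an electromagnetic simulation of the coil/body setup
into a small stack of Hermitian positive-semidefinite matrices; the maximum
over VOPs of the quadratic form p^H V p upper-bounds the 10g-local SAR for
channel voltage vector p.  Time-averaging over the sequence repetition time
turns per-sample power into W/kg.  VOP generation/compression is out of
scope here: matrices are read from file or synthesized.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.io

from . import autodiff as ad
from .pulse import PulseWaveform

__all__ = ["VOPSet", "local_sar", "read_vops", "write_vops"]


@dataclasses.dataclass
class VOPSet:
    """Stack of Hermitian PSD matrices [W/kg per V^2], shape (n_vops, n_ch, n_ch)."""

    matrices: np.ndarray
    overestimation_factor: float | None = None

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=np.complex128)
        if self.matrices.ndim == 2:
            self.matrices = self.matrices[None]
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError(
                f"VOP stack must have shape (n_vops, n, n), got {self.matrices.shape}"
            )
        norm = np.abs(self.matrices).max()
        asym = np.abs(self.matrices - self.matrices.conj().transpose(0, 2, 1)).max()
        if asym > 1e-12 * max(norm, 1e-300):
            raise ValueError(f"VOP matrices not Hermitian (asymmetry {asym:.3g})")

    @property
    def n_vops(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


def local_sar(pulse: PulseWaveform, vops: VOPSet, tr: float) -> float:
    """Maximum local SAR [W/kg] of `pulse` repeated every `tr` seconds.

    Computes max over VOPs v of (raster/tr) * sum_t p(t)^H V_v p(t): the pulse
    samples contribute, the dead time of the TR contributes zero.
    """
    if tr < pulse.duration:
        raise ValueError(
            f"tr ({tr} s) shorter than the pulse duration ({pulse.duration} s): "
            "duty cycle would exceed 1"
        )
    if pulse.n_channels != vops.n_channels:
        raise ValueError(
            f"pulse has {pulse.n_channels} channels but VOPs are "
            f"{vops.n_channels}x{vops.n_channels}"
        )
    p = pulse.rf  # (nc, nt)
    quad = np.einsum("ct,vcd,dt->v", p.conj(), vops.matrices, p).real
    return float(quad.max() * pulse.raster / tr)


def local_sar_core(rf_re, rf_im, vops: VOPSet, raster: float, tr: float):
    """Differentiable max-over-VOPs SAR from real/imag RF sample arrays.

    Accepts plain arrays or autodiff Tensors of shape (n_channels, n_samples).
    For Hermitian V = Vr + i Vi (Vr symmetric, Vi antisymmetric) the real
    quadratic form is a^T Vr a + b^T Vr b + 2 b^T Vi a with p = a + i b.
    """
    nv, nc = vops.n_vops, vops.n_channels
    vr = np.ascontiguousarray(vops.matrices.real.reshape(nv * nc, nc))
    vi = np.ascontiguousarray(vops.matrices.imag.reshape(nv * nc, nc))
    # (nv*nc, nt) -> (nv, nc, nt)
    shape3 = (nv, nc, -1)
    vra = ad.reshape(vr @ rf_re, shape3)
    vrb = ad.reshape(vr @ rf_im, shape3)
    via = ad.reshape(vi @ rf_re, shape3)
    a3 = ad.reshape(rf_re, (1, nc, -1))
    b3 = ad.reshape(rf_im, (1, nc, -1))
    per_vop = ad.asum(a3 * vra + b3 * vrb + 2.0 * (b3 * via), axis=(1, 2))
    return ad.amax(per_vop) * (raster / tr)


def read_vops(path, key: str = "VOP") -> VOPSet:
    """Read a VOP stack from a MATLAB container.

    The container holds a complex array of shape
    ``(n_channels, n_channels, n_vops)`` (a single 2-D matrix is accepted).
    Matrices are Hermitianized on load; a warning is emitted if the asymmetry
    exceeds 1e-9 of the matrix norm.
    """
    contents = scipy.io.loadmat(path)
    if key not in contents:
        raise ValueError(f"VOP file {path} is missing array '{key}'")
    arr = np.asarray(contents[key], dtype=np.complex128)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"VOP array must be (n, n, n_vops), got shape {arr.shape}")
    mats = np.moveaxis(arr, 2, 0)
    herm = 0.5 * (mats + mats.conj().transpose(0, 2, 1))
    asym = np.abs(mats - herm).max()
    norm = max(np.abs(mats).max(), 1e-300)
    if asym > 1e-9 * norm:
        warnings.warn(
            f"VOP matrices in {path} deviate from Hermitian symmetry by {asym:.3g}; "
            "Hermitianized on load",
            stacklevel=2,
        )
    return VOPSet(matrices=herm)


def write_vops(vops: VOPSet, path, key: str = "VOP") -> None:
    """Write the VOP stack as (n_channels, n_channels, n_vops)."""
    scipy.io.savemat(path, {key: np.moveaxis(vops.matrices, 0, 2)})
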