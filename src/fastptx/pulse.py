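"""Waveform container shared by simulators, designers and file I/O."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["PulseWaveform"]


@dataclasses.dataclass
class PulseWaveform:
    """Per-channel complex RF [V] and 3-axis gradient [T/m] samples.

    ``rf`` has shape ``(n_channels, n_samples)``, ``grad`` has shape
    ``(3, n_samples)``; both live on the common raster ``raster`` [s].
    """

    rf: np.ndarray
    grad: np.ndarray
    raster: float

    def __post_init__(self):
        self.rf = np.atleast_2d(np.asarray(self.rf, dtype=np.complex128))
        self.grad = np.atleast_2d(np.asarray(self.grad, dtype=np.float64))
        self.raster = float(self.raster)
        if self.grad.shape[0] != 3:
            raise ValueError(f"grad must have shape (3, n_samples), got {self.grad.shape}")
        if self.rf.shape[1] != self.grad.shape[1]:
            raise ValueError(
                f"rf and grad sample counts differ: {self.rf.shape[1]} vs {self.grad.shape[1]}"
            )
        if not self.raster > 0:
            raise ValueError(f"raster must be positive, got {self.raster}")
        if not (np.all(np.isfinite(self.rf)) and np.all(np.isfinite(self.grad))):
            raise ValueError("waveforms contain non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.rf.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rf.shape[1]

    @property
    def duration(self) -> float:
        """Total duration [s]."""
        return self.n_samples * self.raster

    def scaled(self, factor: complex) -> "PulseWaveform":
        """Return a copy with RF multiplied by `factor` (gradients unchanged)."""
        return PulseWaveform(rf=self.rf * factor, grad=self.grad.copy(), raster=self.raster)

    def copy(self) -> "PulseWaveform":
        return PulseWaveform(rf=self.rf.copy(), grad=self.grad.copy(), raster=self.raster)
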