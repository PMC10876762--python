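"""ini-style text serialization of pTx pulses.

The dialect is this package's own (vendor pulse formats are proprietary):
a ``[pTXPulse]`` header section, one ``[Gradient]`` section with a row per
sample ("gx gy gz" in mT/m) and one ``[RF_ch<k>]`` section per channel with
rows "magnitude_V phase_deg".  Values carry 9 significant digits, so a
read-back matches the written pulse to that precision.  RF is stored as
magnitude/phase for human auditability even though the optimizer works on
real/imaginary parts.
"""

from __future__ import annotations

import configparser
import dataclasses

import numpy as np

from .pulse import PulseWaveform

__all__ = ["PulseFileHeader", "PulseFileError", "write_pulse_ini", "read_pulse_ini"]


class PulseFileError(ValueError):
    """Raised for malformed pulse files."""


@dataclasses.dataclass
class PulseFileHeader:
    """Pulse file metadata; must stay consistent with the sample blocks."""

    n_channels: int
    n_samples: int
    raster: float
    nominal_fa: float = 0.0
    comment: str = ""

    @classmethod
    def for_pulse(cls, pulse: PulseWaveform, nominal_fa: float = 0.0,
                  comment: str = "") -> "PulseFileHeader":
        return cls(
            n_channels=pulse.n_channels,
            n_samples=pulse.n_samples,
            raster=pulse.raster,
            nominal_fa=nominal_fa,
            comment=comment,
        )


def write_pulse_ini(pulse: PulseWaveform, header: PulseFileHeader, path) -> None:
    """Write `pulse` to an ini-style text file."""
    if not (np.all(np.isfinite(pulse.rf)) and np.all(np.isfinite(pulse.grad))):
        raise PulseFileError("waveforms contain non-finite samples")
    if header.n_channels != pulse.n_channels or header.n_samples != pulse.n_samples:
        raise PulseFileError(
            f"header geometry ({header.n_channels} ch, {header.n_samples} samples) "
            f"does not match the pulse ({pulse.n_channels} ch, {pulse.n_samples})"
        )
    cfg = configparser.ConfigParser()
    cfg.optionxform = str
    cfg["pTXPulse"] = {
        "n_channels": str(header.n_channels),
        "n_samples": str(header.n_samples),
        "raster_s": f"{header.raster:.9g}",
        "nominal_fa_deg": f"{header.nominal_fa:.9g}",
        "comment": header.comment,
    }
    cfg["Gradient"] = {
        f"s{i}": " ".join(f"{g * 1e3:.9g}" for g in pulse.grad[:, i])
        for i in range(pulse.n_samples)
    }
    mag = np.abs(pulse.rf)
    phase = np.degrees(np.angle(pulse.rf))
    for c in range(pulse.n_channels):
        cfg[f"RF_ch{c}"] = {
            f"s{i}": f"{mag[c, i]:.9g} {phase[c, i]:.9g}"
            for i in range(pulse.n_samples)
        }
    with open(path, "w") as fh:
        cfg.write(fh)


def read_pulse_ini(path):
    """Read an ini-style pulse file; returns (PulseWaveform, PulseFileHeader)."""
    cfg = configparser.ConfigParser()
    cfg.optionxform = str
    read = cfg.read(path)
    if not read:
        raise PulseFileError(f"cannot read pulse file {path}")
    if "pTXPulse" not in cfg:
        raise PulseFileError(f"{path}: missing [pTXPulse] section")
    head = cfg["pTXPulse"]
    try:
        header = PulseFileHeader(
            n_channels=int(head["n_channels"]),
            n_samples=int(head["n_samples"]),
            raster=float(head["raster_s"]),
            nominal_fa=float(head.get("nominal_fa_deg", "0")),
            comment=head.get("comment", ""),
        )
    except KeyError as exc:
        raise PulseFileError(f"{path}: missing header field {exc}") from exc

    def rows(section: str, n_cols: int) -> np.ndarray:
        if section not in cfg:
            raise PulseFileError(f"{path}: missing [{section}] section")
        sec = cfg[section]
        if len(sec) != header.n_samples:
            raise PulseFileError(
                f"{path}: [{section}] has {len(sec)} rows, header says "
                f"{header.n_samples}"
            )
        out = np.empty((header.n_samples, n_cols))
        for i in range(header.n_samples):
            key = f"s{i}"
            if key not in sec:
                raise PulseFileError(f"{path}: [{section}] is missing row {key}")
            vals = sec[key].split()
            if len(vals) != n_cols:
                raise PulseFileError(
                    f"{path}: [{section}] row {key} has {len(vals)} columns, "
                    f"expected {n_cols}"
                )
            out[i] = [float(v) for v in vals]
        return out

    grad = rows("Gradient", 3).T * 1e-3  # mT/m -> T/m
    rf = np.empty((header.n_channels, header.n_samples), dtype=np.complex128)
    for c in range(header.n_channels):
        mp = rows(f"RF_ch{c}", 2)
        rf[c] = mp[:, 0] * np.exp(1j * np.radians(mp[:, 1]))
    return PulseWaveform(rf=rf, grad=grad, raster=header.raster), header
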