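"""Composite design cost: FA fidelity plus hardware/regulatory terms.

The total cost is the plain sum of eight terms: an RMS flip-angle error
(degrees), hinge-squared *error* terms that are exactly zero while the
per-channel voltage, gradient magnitude, slew rate, gradient edge samples and
local SAR stay inside their limits, and small always-on *penalty* terms for
average RF power and slew activity.  The numeric weights follow the toolbox
convention (1e6 on voltage/slew violations, 1e15 on gradient-magnitude
violations, 1e3 on edge samples before squaring, 1e-2 on |p| and 1e-6 on
|dg/dt|^2 in the penalties, 1e2 on SAR violations): violations dominate any
fidelity gain, penalties stay of order one.

Hinge terms reduce by SUM over violating samples so that every violating
sample receives gradient pressure; set ``hinge_reduction="mean"`` to average
instead.  The slew rate is the forward difference of the gradient waveform
divided by the raster, including the ramps from/to the implicit zero before
the first and after the last sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .pulse import PulseWaveform
from .sar import VOPSet, local_sar_core

__all__ = ["Limits", "CostWeights", "CostBreakdown", "cost_terms", "total_cost"]

_TINY = 1e-60


@dataclasses.dataclass
class Limits:
    """Hardware and regulatory limits with head-coil defaults.

    u_limit: peak RF magnitude per channel [V]; g_limit: gradient magnitude
    [T/m]; s_limit: slew rate [T/m/s]; sar_limit: max local SAR [W/kg];
    tr: average pulse repetition time [s] for the SAR duty cycle.
    """

    u_limit: float = 185.0
    g_limit: float = 65e-3
    s_limit: float = 185.0
    sar_limit: float = 2.3
    tr: float = 19.7e-3

    def __post_init__(self):
        for name in ("u_limit", "g_limit", "s_limit", "sar_limit", "tr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, factor: float) -> "Limits":
        """Copy with the voltage limit scaled (used by the large-FA recipe)."""
        return dataclasses.replace(self, u_limit=self.u_limit * factor)


@dataclasses.dataclass
class CostWeights:
    """Multiplier of each term; defaults reproduce the printed formulas."""

    rmse: float = 1.0
    volt: float = 1e6
    maxg: float = 1e15
    slew: float = 1e6
    edge: float = 1e6  # ((g_first + g_last) * 1e3)^2
    power: float = 1e-4  # (|p| * 1e-2)^2
    slew_pen: float = 1e-6
    sar: float = 1e2

    @classmethod
    def from_ini(cls, path) -> "CostWeights":
        """Load weights from a ``[weights]`` section of an ini file; fields
        not present keep their defaults."""
        import configparser

        cfg = configparser.ConfigParser()
        if not cfg.read(path):
            raise ValueError(f"cannot read weight config {path}")
        if "weights" not in cfg:
            raise ValueError(f"{path}: missing [weights] section")
        known = {f.name for f in dataclasses.fields(cls)}
        values = {}
        for key, val in cfg["weights"].items():
            if key not in known:
                raise ValueError(f"{path}: unknown weight {key!r}")
            values[key] = float(val)
        return cls(**values)


@dataclasses.dataclass
class CostBreakdown:
    """The eight cost terms; ``total`` is their sum."""

    pen_rmse: float
    err_volt: float
    err_maxG: float
    err_slew: float
    err_edge: float
    pen_power: float
    pen_slew: float
    err_sar: float

    _ORDER = (
        "pen_rmse", "err_volt", "err_maxG", "err_slew",
        "err_edge", "pen_power", "pen_slew", "err_sar",
    )

    @property
    def total(self) -> float:
        return total_cost(self)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._ORDER}
        d["total"] = self.total
        return d


def total_cost(breakdown: CostBreakdown) -> float:
    """Exact sum of the eight terms."""
    return float(sum(getattr(breakdown, k) for k in CostBreakdown._ORDER))


# ----------------------------------------------------------------------
# backend-generic kernel
# ----------------------------------------------------------------------

def _slew(grad, raster: float, n_samples: int):
    """Forward-difference slew [T/m/s], (3, n_samples+1), with zero boundaries."""
    zero = np.zeros((3, 1))
    padded_hi = ad.concatenate([grad, zero], axis=1)
    padded_lo = ad.concatenate([zero, grad], axis=1)
    return (padded_hi - padded_lo) * (1.0 / raster)


def cost_terms_core(
    rf_re,
    rf_im,
    grad,
    fa_deg,
    target_fa_deg: np.ndarray,
    limits: Limits,
    raster: float,
    vops: VOPSet | None = None,
    weights: CostWeights | None = None,
    hinge_reduction: str = "sum",
):
    """All eight terms from waveform arrays/Tensors and a (masked) FA map.

    Returns a dict of scalars (floats or autodiff Tensors).  ``fa_deg`` and
    ``target_fa_deg`` are flat arrays over masked voxels, in degrees.
    """
    w = weights or CostWeights()
    if hinge_reduction == "sum":
        reduce_hinge = ad.asum
    elif hinge_reduction == "mean":
        reduce_hinge = ad.amean
    else:
        raise ValueError(f"unknown hinge_reduction {hinge_reduction!r}")

    nt = rf_re.shape[1] if not isinstance(rf_re, ad.Tensor) else rf_re.data.shape[1]

    dfa = fa_deg - np.abs(target_fa_deg)
    pen_rmse = ad.sqrt(ad.amean(dfa * dfa) + _TINY) * w.rmse

    p_abs = ad.sqrt(rf_re * rf_re + rf_im * rf_im + _TINY)
    over_v = ad.relu(p_abs - limits.u_limit)
    err_volt = reduce_hinge(over_v * over_v) * w.volt

    g_abs = ad.sqrt(grad * grad + _TINY)
    over_g = ad.relu(g_abs - limits.g_limit)
    err_maxg = reduce_hinge(over_g * over_g) * w.maxg

    sl = _slew(grad, raster, nt)
    sl_abs = ad.sqrt(sl * sl + _TINY)
    over_s = ad.relu(sl_abs - limits.s_limit)
    err_slew = reduce_hinge(over_s * over_s) * w.slew

    edge = grad[:, 0] + grad[:, nt - 1]
    err_edge = ad.asum(edge * edge) * w.edge

    pen_power = ad.amean(rf_re * rf_re + rf_im * rf_im) * w.power

    pen_slew = ad.amean(sl * sl) * w.slew_pen

    if vops is not None:
        sar = local_sar_core(rf_re, rf_im, vops, raster, limits.tr)
        over_sar = ad.relu(sar - limits.sar_limit)
        err_sar = over_sar * over_sar * w.sar
    else:
        sar = 0.0
        err_sar = 0.0

    return {
        "pen_rmse": pen_rmse,
        "err_volt": err_volt,
        "err_maxG": err_maxg,
        "err_slew": err_slew,
        "err_edge": err_edge,
        "pen_power": pen_power,
        "pen_slew": pen_slew,
        "err_sar": err_sar,
        "sar": sar,
    }


def cost_terms(
    pulse: PulseWaveform,
    sim_fa: np.ndarray,
    target_fa,
    mask: np.ndarray | None,
    limits: Limits,
    vops: VOPSet | None = None,
    weights: CostWeights | None = None,
    hinge_reduction: str = "sum",
) -> CostBreakdown:
    """Evaluate the breakdown for a pulse and a simulated FA map [deg].

    ``sim_fa``/``target_fa`` may be full grids (with ``mask``) or flat masked
    arrays (``mask=None``); a scalar target is broadcast.
    """
    fa = np.asarray(sim_fa, dtype=np.float64)
    target = np.broadcast_to(np.asarray(target_fa, dtype=np.float64), fa.shape)
    if mask is not None:
        fa = fa[mask]
        target = target[mask]
    terms = cost_terms_core(
        np.ascontiguousarray(pulse.rf.real),
        np.ascontiguousarray(pulse.rf.imag),
        pulse.grad,
        fa,
        target,
        limits,
        pulse.raster,
        vops=vops,
        weights=weights,
        hinge_reduction=hinge_reduction,
    )
    return CostBreakdown(**{k: float(terms[k]) for k in CostBreakdown._ORDER})
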