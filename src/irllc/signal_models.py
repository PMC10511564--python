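"""Closed-form magnitude signal models for inversion-recovery imaging.

The magnitude Look-Locker signal is modeled with the standard
three-parameter inversion-recovery form

    S(TI) = |A - B * exp(-TI / T1*)|

where ``A`` is the equilibrium amplitude, ``B`` the inversion amplitude and
``T1*`` the apparent relaxation time under continuous Look-Locker readout.
Ideal inversion with an unperturbing readout corresponds to ``B/A = 2`` and
``T1* = T1``; in general the true relaxation time is recovered with the
Look-Locker correction ``T1 = T1* * (B/A - 1)``.

The spoiled-gradient-echo (VIBE-type) comparator uses the steady-state
Ernst signal equation; T2*/TE decay is deliberately not modeled because
lesion-to-liver contrast in this package is driven by T1 differences only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IRModel",
    "SPGRParams",
    "ir_magnitude",
    "null_ti",
    "ll_correct",
    "spgr_signal",
]


@dataclass(frozen=True)
class IRModel:
    """Three-parameter magnitude inversion-recovery model.

    Parameters
    ----------
    a : float
        Equilibrium amplitude ``A`` (arbitrary units, > 0).
    b : float
        Inversion amplitude ``B`` (arbitrary units, > 0).  ``B/A = 2``
        corresponds to a perfect 180-degree inversion with no readout
        perturbation.
    t1_star_ms : float
        Apparent relaxation time ``T1*`` in milliseconds (> 0).
    """

    a: float
    b: float
    t1_star_ms: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"equilibrium amplitude a must be > 0, got {self.a}")
        if not (self.b > 0):
            raise ValueError(f"inversion amplitude b must be > 0, got {self.b}")
        if not (self.t1_star_ms > 0):
            raise ValueError(f"t1_star_ms must be > 0, got {self.t1_star_ms}")

    @property
    def b_over_a(self) -> float:
        return self.b / self.a

    @property
    def t1_ms(self) -> float:
        """Look-Locker-corrected relaxation time ``T1* * (B/A - 1)``."""
        return ll_correct(self)


@dataclass(frozen=True)
class SPGRParams:
    """Spoiled gradient-echo acquisition parameters.

    Defaults mirror a typical unenhanced 3D T1-VIBE protocol
    (TR = 3.5 ms, flip angle 10 degrees).
    """

    tr_ms: float = 3.5
    flip_deg: float = 10.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tr_ms > 0):
            raise ValueError(f"tr_ms must be > 0, got {self.tr_ms}")
        if not (0 < self.flip_deg <= 90):
            raise ValueError(f"flip_deg must be in (0, 90], got {self.flip_deg}")
        if not (self.m0 > 0):
            raise ValueError(f"m0 must be > 0, got {self.m0}")


def ir_magnitude(ti_ms, model: IRModel):
    """Magnitude inversion-recovery signal ``|A - B exp(-TI/T1*)|``.

    ``ti_ms`` may be a scalar or array of inversion times (ms, >= 0).
    Returns a value (or array) with the same shape, always >= 0.
    """
    ti = np.asarray(ti_ms, dtype=float)
    if np.any(ti < 0):
        raise ValueError("inversion time must be non-negative")
    out = np.abs(model.a - model.b * np.exp(-ti / model.t1_star_ms))
    if np.isscalar(ti_ms) or np.ndim(ti_ms) == 0:
        return float(out)
    return out


def null_ti(model: IRModel) -> float:
    """Inversion time at which the magnitude signal crosses zero.

    The null point ``TI = T1* ln(B/A)`` exists only when ``B > A``;
    otherwise the recovery curve never changes sign and a ``ValueError``
    is raised.
    """
    if model.b <= model.a:
        raise ValueError(
            "no null point exists: recovery does not cross zero unless b > a "
            f"(got b/a = {model.b / model.a:.4g})"
        )
    return model.t1_star_ms * math.log(model.b / model.a)


def ll_correct(fit: IRModel) -> float:
    """Look-Locker correction ``T1 = T1* (B/A - 1)``.

    Converts the apparent relaxation time of a continuously sampled
    Look-Locker experiment to the true longitudinal relaxation time.
    With ideal inversion (``B/A = 2``) the correction is the identity.
    """
    return fit.t1_star_ms * (fit.b / fit.a - 1.0)


def spgr_signal(t1_ms, p: SPGRParams = SPGRParams()):
    """Steady-state spoiled gradient-echo signal.

    ``S = M0 sin(alpha) (1 - E1) / (1 - cos(alpha) E1)`` with
    ``E1 = exp(-TR/T1)``.  Strictly decreasing in T1 for fixed TR and
    flip angle, so long-T1 lesions appear hypointense on T1-VIBE.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be > 0")
    alpha = math.radians(p.flip_deg)
    e1 = np.exp(-p.tr_ms / t1)
    out = p.m0 * math.sin(alpha) * (1.0 - e1) / (1.0 - math.cos(alpha) * e1)
    if np.isscalar(t1_ms) or np.ndim(t1_ms) == 0:
        return float(out)
    return out
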