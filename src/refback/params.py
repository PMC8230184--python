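"""Diffusion-decision-model parameter container.

Parameters follow the modern convention with the within-trial diffusion
coefficient fixed at s = 1; drift rates and boundary separation are
interpreted on that scale.  Start point ``z`` and its variability ``sz``
are expressed as fractions of the boundary separation ``a``, so a single
start-point parameter remains meaningful when ``a`` differs between
conditions.  Drift criterion and non-decision-time variability are fixed
at zero and rejected if set otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised when a diffusion parameter is outside its domain."""


@dataclass(frozen=True)
class DDMParams:
    """One design cell's diffusion parameters.

    Attributes
    ----------
    v : float
        Mean drift rate (evidence/s), signed toward the upper boundary.
    a : float
        Boundary separation (> 0).
    z : float
        Relative start point, fraction of ``a`` in (0, 1).
    t0 : float
        Non-decision time in seconds (>= 0).
    sv : float
        SD of across-trial Gaussian drift variability (>= 0).
    sz : float
        Width of uniform across-trial start-point variability,
        fraction of ``a`` (>= 0); requires z +/- sz/2 inside (0, 1).
    dc, st0 : float
        Drift criterion and non-decision-time variability; both fixed
        at zero.
    """

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.0
    sv: float = 0.0
    sz: float = 0.0
    dc: float = 0.0
    st0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ParameterError(f"relative start point z must be in (0,1), got {self.z}")
        if self.t0 < 0:
            raise ParameterError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if self.sv < 0:
            raise ParameterError(f"drift variability sv must be >= 0, got {self.sv}")
        if self.sz < 0:
            raise ParameterError(f"start-point variability sz must be >= 0, got {self.sz}")
        if not (self.z - self.sz / 2 > 0 and self.z + self.sz / 2 < 1):
            raise ParameterError(
                f"start-point range z +/- sz/2 must lie inside (0,1); "
                f"got z={self.z}, sz={self.sz}"
            )
        if self.dc != 0.0:
            raise ParameterError("drift criterion dc is fixed at zero")
        if self.st0 != 0.0:
            raise ParameterError("non-decision-time variability st0 is fixed at zero")
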