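"""Firing-rate activation functions.

The activation maps the membrane drive (weighted sum of presynaptic drives
plus the threshold input, in volts) to an instantaneous firing rate.  Three
forms are supported:

``halfwave``
    continuous half-wave rectification, ``f(x) = max(x, 0)``.  Unbounded
    above; ``f_max`` is ignored.
``sigmoid``
    the logistic ``f(x) = f_max * exp(g*x) / (1 + exp(g*x))`` with slope
    parameter ``gamma`` (per volt) and ceiling ``f_max``.
``saturating_linear``
    0 below 0, identity on ``[0, f_max]``, clipped at ``f_max`` above.

Derivatives of the nonsmooth activations use the right-hand limit at 0 (and
the left-hand limit at ``f_max`` for the saturating-linear form), so the
derivative is 1 on the closed linear branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

_KINDS = ("halfwave", "sigmoid", "saturating_linear")


@dataclass(frozen=True)
class ActivationSpec:
    """Specification of a firing-rate nonlinearity.

    Parameters
    ----------
    kind:
        One of ``halfwave``, ``sigmoid``, ``saturating_linear``.
    f_max:
        Maximum firing rate (dimensionless rate).  Must be positive.
        Ignored by ``halfwave``.
    gamma:
        Slope of the sigmoid (per volt).  Used by ``sigmoid`` only.
    """

    kind: str
    f_max: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown activation kind {self.kind!r}; expected one of {_KINDS}")
        if not self.f_max > 0:
            raise ValueError("f_max must be positive")
        if self.kind == "sigmoid" and not self.gamma > 0:
            raise ValueError("gamma must be positive for the sigmoid activation")

    @property
    def bounded(self) -> bool:
        """Whether outputs are guaranteed to lie in ``[0, f_max]``."""
        return self.kind != "halfwave"


def _check_finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation input must be finite")
    return x


def activation_eval(spec: ActivationSpec, x):
    """Evaluate the firing rate at membrane drive ``x`` (scalar or array)."""
    x = _check_finite(x)
    if spec.kind == "halfwave":
        return np.maximum(x, 0.0)
    if spec.kind == "sigmoid":
        return spec.f_max * expit(spec.gamma * x)
    return np.clip(x, 0.0, spec.f_max)


def activation_derivative(spec: ActivationSpec, x):
    """Slope of the activation at ``x``.

    For the sigmoid this is the exact ``gamma * f * (1 - f / f_max)``
    identity; for the piecewise-linear forms it is the indicator of the
    linear branch with the kink convention documented in the module
    docstring.
    """
    x = _check_finite(x)
    if spec.kind == "halfwave":
        return (x >= 0.0).astype(float)
    if spec.kind == "sigmoid":
        f = spec.f_max * expit(spec.gamma * x)
        return spec.gamma * f * (1.0 - f / spec.f_max)
    return ((x >= 0.0) & (x <= spec.f_max)).astype(float)
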