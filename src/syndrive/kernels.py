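"""Postsynaptic-potential kernels.

The kernel alpha(t) is the dimensionless voltage response to a single spike.
Two shapes are supported:

``exponential``
    alpha(t) = B * exp(-t / lam).  Peaks instantly; total area B * lam.
    Drives built from it obey the first-order network model.
``erlang``
    alpha(t) = B * t * exp(-t / lam).  Zero at t = 0, peaks at t = lam,
    total area B * lam**2; captures the delayed peak of real postsynaptic
    potentials and yields the second-order network model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_KINDS = ("exponential", "erlang")


@dataclass(frozen=True)
class KernelSpec:
    """Postsynaptic kernel: kind, dimensionless gain ``B``, decay ``lam`` (s)."""

    kind: str
    B: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected one of {_KINDS}")
        if not self.B > 0:
            raise ValueError("kernel gain B must be positive")
        if not self.lam > 0:
            raise ValueError("kernel time constant lam must be positive")


def kernel_eval(spec: KernelSpec, t):
    """Evaluate alpha(t); zero for t < 0."""
    t = np.asarray(t, dtype=float)
    decay = np.exp(-np.maximum(t, 0.0) / spec.lam)
    if spec.kind == "exponential":
        val = spec.B * decay
    else:
        val = spec.B * np.maximum(t, 0.0) * decay
    return np.where(t < 0.0, 0.0, val)
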