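"""Seeded synthetic-network generator.

Networks are drawn with the structural assumptions of the reference models:
block sign conventions (excitatory weights nonnegative, inhibitory
nonpositive), zero diagonals, and a prescribed number of inhibitory neurons
that receive no inhibitory input (zero ``AII`` row) -- the subset on which
the partial-synchronization analysis rests.

Default ranges mirror the reference experiments: unit-scale synaptic
weights, fast excitatory decay (tens of milliseconds), slower "prolonged"
inhibitory decay (hundreds of milliseconds), small positive thresholds with
larger thresholds for the uninhibited inhibitory subset.  ``heterogeneity``
interpolates between identical within-block weights (0, the mean-field
regime) and the full sampled spread (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activations import ActivationSpec
from .network import NeuronalNetwork


@dataclass
class GeneratorSpec:
    """Parameters of the random-network generator.

    ``q_zero`` is the requested size of the no-inhibitory-input subset
    (the last ``q_zero`` inhibitory neurons get an all-zero ``AII`` row;
    the others are guaranteed at least one inhibitory input).
    """

    nE: int = 4
    nI: int = 4
    q_zero: int = 2
    density: float = 0.5
    weight_range: tuple[float, float] = (0.5, 1.5)
    lamE_range: tuple[float, float] = (0.04, 0.06)
    lamI_range: tuple[float, float] = (0.3, 0.5)
    vthE_range: tuple[float, float] = (0.0, 0.05)
    vthI_range: tuple[float, float] = (0.0, 0.5)
    heterogeneity: float = 1.0
    activation: ActivationSpec = field(
        default_factory=lambda: ActivationSpec("saturating_linear", f_max=10.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.q_zero <= self.nI):
            raise ValueError("q_zero must lie in [0, nI]")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")
        if not (0.0 <= self.heterogeneity <= 1.0):
            raise ValueError("heterogeneity must lie in [0, 1]")


def _block(rng, shape, spec: GeneratorSpec, sign: float, zero_diag: bool) -> np.ndarray:
    lo, hi = spec.weight_range
    mid = 0.5 * (lo + hi)
    w = rng.uniform(lo, hi, size=shape)
    w = mid + spec.heterogeneity * (w - mid)
    mask = rng.random(shape) < spec.density
    M = sign * w * mask
    if zero_diag:
        np.fill_diagonal(M, 0.0)
    return M


def generate_network(spec: GeneratorSpec) -> NeuronalNetwork:
    """Draw a structurally valid network, reproducible from ``spec.seed``.

    The generated network always passes validation and partitions with a
    no-inhibitory-input subset of exactly ``q_zero`` neurons (placed last
    among the inhibitory indices).
    """
    nI_recv = spec.nI - spec.q_zero
    if nI_recv > 0 and spec.nI < 2:
        raise ValueError("an inhibitory neuron cannot receive inhibitory input "
                         "in a network with a single inhibitory neuron")
    rng = np.random.default_rng(spec.seed)
    AEE = _block(rng, (spec.nE, spec.nE), spec, +1.0, zero_diag=True)
    AEI = _block(rng, (spec.nE, spec.nI), spec, -1.0, zero_diag=False)
    AIE = _block(rng, (spec.nI, spec.nE), spec, +1.0, zero_diag=False)
    AII = _block(rng, (spec.nI, spec.nI), spec, -1.0, zero_diag=True)
    AII[nI_recv:, :] = 0.0
    lo, hi = spec.weight_range
    mid = 0.5 * (lo + hi)
    for i in range(nI_recv):
        if not np.any(AII[i] != 0.0):
            choices = [j for j in range(spec.nI) if j != i]
            AII[i, rng.choice(choices)] = -(
                mid + spec.heterogeneity * (rng.uniform(lo, hi) - mid))

    def vec(rng_range, n):
        return rng.uniform(*rng_range, size=n)

    return NeuronalNetwork(
        AEE=AEE, AEI=AEI, AIE=AIE, AII=AII,
        lamE=vec(spec.lamE_range, spec.nE), lamI=vec(spec.lamI_range, spec.nI),
        vthE=vec(spec.vthE_range, spec.nE), vthI=vec(spec.vthI_range, spec.nI),
        activation=spec.activation)
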