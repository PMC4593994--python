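"""Network containers, structural validation, and the inhibitory-subset partition.

A :class:`NeuronalNetwork` holds the block connectivity of an excitatory/
inhibitory population: ``AEE`` and ``AIE`` carry nonnegative weights (volts)
from excitatory neurons, ``AEI`` and ``AII`` carry nonpositive weights from
inhibitory neurons, and the diagonals of ``AEE``/``AII`` are zero (no
self-coupling).  Per-neuron decay time constants, firing-rate gains,
threshold inputs, and the shared activation complete the model.

:func:`partition_inhibitory` identifies the inhibitory neurons whose ``AII``
row is entirely zero -- they receive no inhibitory input -- permutes them
last, and assembles the reduced operators used by the synchronization
certificates: the coupled subsystem matrix ``Atilde`` (excitatory neurons
plus the ``q`` inhibitory neurons that do receive inhibition), the feed
matrix ``Btilde`` from the uninhibited subset, and their second-order
(Erlang-kernel) companion-form counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .activations import ActivationSpec

ThresholdLike = Callable[[float], np.ndarray] | np.ndarray | Sequence[float] | float


def _as_vector(x, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1 and n > 1:
        arr = np.full(n, float(arr[0]))
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class NeuronalNetwork:
    """Block-structured excitatory/inhibitory synaptic-drive network.

    Threshold inputs ``vthE``/``vthI`` may be constant vectors or callables
    ``t -> vector`` for time-varying sensory input.
    """

    AEE: np.ndarray
    AEI: np.ndarray
    AIE: np.ndarray
    AII: np.ndarray
    lamE: np.ndarray
    lamI: np.ndarray
    vthE: ThresholdLike
    vthI: ThresholdLike
    activation: ActivationSpec
    BE: np.ndarray | float = 1.0
    BI: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.AEE = np.asarray(self.AEE, dtype=float)
        self.AEI = np.asarray(self.AEI, dtype=float)
        self.AIE = np.asarray(self.AIE, dtype=float)
        self.AII = np.asarray(self.AII, dtype=float)
        if self.AEE.ndim != 2 or self.AEE.shape[0] != self.AEE.shape[1]:
            raise ValueError("AEE must be a square matrix")
        if self.AII.ndim != 2 or self.AII.shape[0] != self.AII.shape[1]:
            raise ValueError("AII must be a square matrix")
        nE, nI = self.AEE.shape[0], self.AII.shape[0]
        if self.AEI.shape != (nE, nI):
            raise ValueError(f"AEI must have shape {(nE, nI)}, got {self.AEI.shape}")
        if self.AIE.shape != (nI, nE):
            raise ValueError(f"AIE must have shape {(nI, nE)}, got {self.AIE.shape}")
        self.lamE = _as_vector(self.lamE, nE, "lamE")
        self.lamI = _as_vector(self.lamI, nI, "lamI")
        self.BE = _as_vector(self.BE, nE, "BE")
        self.BI = _as_vector(self.BI, nI, "BI")
        if not callable(self.vthE):
            self.vthE = _as_vector(self.vthE, nE, "vthE")
        if not callable(self.vthI):
            self.vthI = _as_vector(self.vthI, nI, "vthI")

    @property
    def nE(self) -> int:
        return self.AEE.shape[0]

    @property
    def nI(self) -> int:
        return self.AII.shape[0]

    @property
    def n(self) -> int:
        return self.nE + self.nI

    @property
    def A(self) -> np.ndarray:
        """Full (nE+nI) x (nE+nI) connectivity matrix, E block first."""
        return np.block([[self.AEE, self.AEI], [self.AIE, self.AII]])

    def vthE_at(self, t: float) -> np.ndarray:
        return np.asarray(self.vthE(t), dtype=float) if callable(self.vthE) else self.vthE

    def vthI_at(self, t: float) -> np.ndarray:
        return np.asarray(self.vthI(t), dtype=float) if callable(self.vthI) else self.vthI

    def constant_thresholds(self) -> bool:
        return not (callable(self.vthE) or callable(self.vthI))


@dataclass
class ValidationReport:
    """Outcome of structural validation: pass/fail plus indexed violations."""

    passed: bool
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def validate_network(net: NeuronalNetwork) -> ValidationReport:
    """Check the sign conventions and structural invariants of the network.

    Shape errors are raised at construction time; this reports sign/diagonal
    violations with their indices.  A warning (not a violation) is recorded
    when the unbounded half-wave activation is used, since the boundedness
    arguments behind the invariant-box and time-constant results assume a
    firing-rate ceiling.
    """
    v: list[str] = []
    for i in range(net.nE):
        if net.AEE[i, i] != 0.0:
            v.append(f"AEE[{i},{i}] = {net.AEE[i, i]} (self-coupling must be zero)")
    for i in range(net.nI):
        if net.AII[i, i] != 0.0:
            v.append(f"AII[{i},{i}] = {net.AII[i, i]} (self-coupling must be zero)")
    for name, M, sign in (("AEE", net.AEE, 1), ("AIE", net.AIE, 1),
                          ("AEI", net.AEI, -1), ("AII", net.AII, -1)):
        bad = np.argwhere(sign * M < 0)
        for i, j in bad:
            v.append(f"{name}[{i},{j}] = {M[i, j]} violates the "
                     f"{'nonnegative' if sign > 0 else 'nonpositive'} sign convention")
    for name, lam in (("lamE", net.lamE), ("lamI", net.lamI)):
        for i in np.nonzero(~(lam > 0))[0]:
            v.append(f"{name}[{i}] = {lam[i]} must be positive")
    for name, B in (("BE", net.BE), ("BI", net.BI)):
        for i in np.nonzero(~(B > 0))[0]:
            v.append(f"{name}[{i}] = {B[i]} must be positive")
    warns = []
    if net.activation.kind == "halfwave":
        warns.append("half-wave activation is unbounded above; results that assume a "
                     "firing-rate ceiling (invariant box, time-constant conditions) do not apply")
    return ValidationReport(passed=not v, violations=v, warnings=warns)


@dataclass
class PartitionedNetwork:
    """Partition of a network around its no-inhibitory-input subset.

    ``permutation`` lists inhibitory indices with the neurons receiving
    inhibitory input first (there are ``q`` of them) and the uninhibited
    subset last; all block operators below refer to that ordering.  The
    hatted second-order operators act on stacked ``[S; dS/dt]`` states.
    """

    net: NeuronalNetwork
    q: int
    permutation: np.ndarray  # inhibitory index order, no-input subset last
    Atilde: np.ndarray       # (nE+q) x (nE+q) coupled-subsystem connectivity
    Btilde: np.ndarray       # (nE+q) x (nI-q) feed from the uninhibited subset
    A2IE: np.ndarray         # (nI-q) x nE drive of the uninhibited subset
    LE: np.ndarray
    L1I: np.ndarray
    L2I: np.ndarray
    Gamma: np.ndarray
    GammaI: np.ndarray
    Ahat: np.ndarray
    Bhat: np.ndarray
    A2IEhat: np.ndarray

    @property
    def nE(self) -> int:
        return self.net.nE

    @property
    def no_input_set(self) -> np.ndarray:
        """Original indices of inhibitory neurons receiving no inhibitory input."""
        return self.permutation[self.q:]

    @property
    def L(self) -> np.ndarray:
        """Decay operator of the coupled subsystem, blockdiag(LE, L1I)."""
        return np.block([
            [self.LE, np.zeros((self.nE, self.q))],
            [np.zeros((self.q, self.nE)), self.L1I]])

    @property
    def A_permuted(self) -> np.ndarray:
        """Full connectivity with inhibitory rows/columns in partition order."""
        idx = np.concatenate([np.arange(self.nE), self.nE + self.permutation])
        return self.net.A[np.ix_(idx, idx)]

    @property
    def L_full(self) -> np.ndarray:
        """Decay operator of the full permuted system, blockdiag(LE, L1I, L2I)."""
        lamI = self.net.lamI[self.permutation]
        return np.diag(np.concatenate([1.0 / self.net.lamE, 1.0 / lamI]))


def _companion(L: np.ndarray) -> np.ndarray:
    n = L.shape[0]
    return np.block([[np.zeros((n, n)), -np.eye(n)], [L @ L, 2.0 * L]])


def _pad_lower_left(M: np.ndarray) -> np.ndarray:
    r, c = M.shape
    return np.block([[np.zeros((r, c)), np.zeros((r, c))],
                     [M, np.zeros((r, c))]])


def partition_inhibitory(net: NeuronalNetwork, tol: float = 0.0) -> PartitionedNetwork:
    """Partition around the maximal set of inhibitory neurons with zero AII row.

    ``tol`` relaxes the zero test for matrices read from lossy text (default
    exact).  The permutation places the no-inhibitory-input subset last;
    reassembling the returned blocks reproduces the permuted connectivity
    exactly.
    """
    row_zero = np.max(np.abs(net.AII), axis=1) <= tol
    receiving = np.nonzero(~row_zero)[0]
    no_input = np.nonzero(row_zero)[0]
    perm = np.concatenate([receiving, no_input]).astype(int)
    q = receiving.size

    AEI_p = net.AEI[:, perm]
    AIE_p = net.AIE[perm, :]
    AII_p = net.AII[np.ix_(perm, perm)]
    A1EI, A2EI = AEI_p[:, :q], AEI_p[:, q:]
    A1IE, A2IE = AIE_p[:q, :], AIE_p[q:, :]
    A1II, A2II = AII_p[:q, :q], AII_p[:q, q:]

    Atilde = np.block([[net.AEE, A1EI], [A1IE, A1II]])
    Btilde = np.vstack([A2EI, A2II])

    lamI_p = net.lamI[perm]
    LE = np.diag(1.0 / net.lamE)
    L1I = np.diag(1.0 / lamI_p[:q])
    L2I = np.diag(1.0 / lamI_p[q:])
    L = np.block([[LE, np.zeros((net.nE, q))], [np.zeros((q, net.nE)), L1I]])

    return PartitionedNetwork(
        net=net, q=q, permutation=perm,
        Atilde=Atilde, Btilde=Btilde, A2IE=A2IE,
        LE=LE, L1I=L1I, L2I=L2I,
        Gamma=_companion(L), GammaI=_companion(L2I),
        Ahat=_pad_lower_left(Atilde), Bhat=_pad_lower_left(Btilde),
        A2IEhat=_pad_lower_left(A2IE),
    )
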