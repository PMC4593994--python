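"""Partial-synchronization certificates and time-constant conditions.

Two complementary routes establish that the coupled part of the network --
all excitatory neurons plus the inhibitory neurons that receive inhibitory
input -- is driven to a synchronized state:

* **LMI certificates.**  Positive-definite ``P``, ``Q`` and diagonal
  positive-definite ``R`` with ``[[Q, -P], [-P, R]] >= 0`` and
  ``Omega = P L + L P - Q - At^T R At > 0`` make ``V = S^T P S`` a strict
  Lyapunov function for the coupled subsystem, proving global exponential
  partial synchronization whenever the threshold premise
  ``vth_tilde <= -Btilde w`` holds.  The second-order (Erlang-kernel) model
  uses the companion-form operators and ``Omega_hat = P Gamma + Gamma^T P
  - Q - Ahat^T R Ahat``.
* **Time-constant conditions.**  For the saturating-linear activation,
  explicit vector inequalities in the inhibitory time constants guarantee
  that every excitatory drive converges to zero: prolonging the time
  constants of the uninhibited inhibitory subset (the in-vitro effect of
  GABAergic anesthetics) makes their drives large enough that the
  inhibition they deliver pins the excitatory population at zero.

Strict vector inequalities ("<< 0" / ">> 0") are tested with a slack of
1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, null_space

from ._sdp import solve_sync_lmi
from .network import NeuronalNetwork, PartitionedNetwork

STRICT_SLACK = 1e-9
DEFAULT_EPSILON = 1e-3


@dataclass
class LMICertificate:
    """A solved or supplied Lyapunov/LMI certificate with its margins."""

    P: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    Omega: np.ndarray
    lambda_min_block: float
    lambda_min_Omega: float
    feasible: bool
    solver_status: str
    order: str = "first"
    semistable_consensus: bool = False  # Omega >= 0 with nullspace spanned by ones


@dataclass
class ConditionReport:
    """Evaluation of a threshold premise or time-constant condition.

    ``premise_flags`` records each stated premise separately; ``holds`` is
    true iff every premise holds and ``lhs_vector`` (when present) is
    elementwise nonpositive.
    """

    holds: bool
    premise_flags: dict[str, bool] = field(default_factory=dict)
    lhs_vector: np.ndarray | None = None
    w: np.ndarray | None = None
    eta: np.ndarray | None = None
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    epsilon: float | None = None
    failing_indices: list[int] = field(default_factory=list)


def _operators(part: PartitionedNetwork, order: str):
    if order == "first":
        return part.Atilde, part.L
    if order == "second":
        return part.Ahat, part.Gamma
    raise ValueError("order must be 'first' or 'second'")


def assemble_omega(P, Q, R, At, Lop) -> np.ndarray:
    """Omega = P*Lop + Lop^T*P - Q - At^T R At (symmetric by construction)."""
    return P @ Lop + Lop.T @ P - Q - At.T @ R @ At


def lmi_feasibility(part: PartitionedNetwork, order: str = "first",
                    margin: float | None = None) -> LMICertificate:
    """Solve the partial-synchronization LMI feasibility problem.

    The internal solver maximizes the joint minimum eigenvalue of the block
    constraint, ``Omega``, ``P`` and ``R``; the problem is declared feasible
    when the achieved ``Omega`` margin exceeds ``margin`` (default
    ``1e-6 * ||L||``) and the block constraint is nonnegative to rounding.
    A certificate with ``0 < lambda_min_Omega <= margin`` is reported
    feasible but flagged marginal in ``solver_status``.
    """
    At, Lop = _operators(part, order)
    if margin is None:
        margin = 1e-6 * np.linalg.norm(Lop, 2)
    sol = solve_sync_lmi(At, Lop)
    P, Q, R = sol["P"], sol["Q"], sol["R"]
    Om = assemble_omega(P, Q, R, At, Lop)
    blk = np.block([[Q, -P], [-P, R]])
    lmin_blk = float(eigh(blk, eigvals_only=True)[0])
    lmin_om = float(eigh(Om, eigvals_only=True)[0])
    lmin_P = float(eigh(P, eigvals_only=True)[0])
    tol = 1e-9 * max(1.0, np.linalg.norm(blk, 2))
    feasible = lmin_blk >= -tol and lmin_om > 0 and lmin_P > 0 and np.min(np.diag(R)) > 0
    status = sol["status"]
    if feasible and lmin_om <= margin:
        status += "; marginal (Omega margin below target)"

    ns = null_space(Om, rcond=1e-8)
    ones = np.ones(Om.shape[0]) / np.sqrt(Om.shape[0])
    semistable = (ns.shape[1] == 1
                  and abs(abs(ns[:, 0] @ ones) - 1.0) < 1e-6
                  and lmin_om > -1e-8)

    return LMICertificate(P=P, Q=Q, R=R, Omega=Om,
                          lambda_min_block=lmin_blk, lambda_min_Omega=lmin_om,
                          feasible=bool(feasible), solver_status=status,
                          order=order, semistable_consensus=bool(semistable))


def verify_certificate(P, Q, R, part: PartitionedNetwork, order: str = "first",
                       tol: float = 1e-8) -> dict:
    """Verify supplied certificate matrices against a partitioned network.

    Certificates of dimension ``nE + q`` (first order) or ``2(nE+q)``
    (second order) are checked against the coupled subsystem; first-order
    certificates of dimension ``nE + nI`` are checked against the full
    permuted system (the formal partition with an empty uninhibited set),
    which is how published certificates for small reference networks are
    stated.  ``pass`` requires the block eigenvalue margin to be >= -tol and
    the ``Omega`` margin > -tol; use a loose ``tol`` (e.g. 0.05) for
    matrices printed to two decimals.
    """
    P, Q, R = (np.asarray(M, dtype=float) for M in (P, Q, R))
    m = P.shape[0]
    n_part = part.nE + part.q
    if order == "second":
        if m != 2 * n_part:
            raise ValueError(f"second-order certificate must be {2 * n_part}x{2 * n_part}")
        At, Lop = part.Ahat, part.Gamma
    elif m == n_part:
        At, Lop = part.Atilde, part.L
    elif m == part.net.n:
        At, Lop = part.A_permuted, part.L_full
    else:
        raise ValueError(f"certificate dimension {m} matches neither the coupled "
                         f"subsystem ({n_part}) nor the full network ({part.net.n})")
    if Q.shape != (m, m) or R.shape != (m, m):
        raise ValueError("P, Q, R must have matching square shapes")
    blk = np.block([[Q, -P], [-P, R]])
    Om = assemble_omega(P, Q, R, At, Lop)
    lmin_blk = float(eigh(blk, eigvals_only=True)[0])
    lmin_om = float(eigh(Om, eigvals_only=True)[0])
    return {"block_lambda_min": lmin_blk, "omega_lambda_min": lmin_om,
            "pass": bool(lmin_blk >= -tol and lmin_om > -tol)}


def _eta(net: NeuronalNetwork, part: PartitionedNetwork) -> np.ndarray:
    """Minimum threshold input of the uninhibited inhibitory subset."""
    if callable(net.vthI):
        raise ValueError("function-valued inhibitory thresholds: supply their minimum "
                         "explicitly by building a network with constant thresholds")
    return net.vthI[part.no_input_set]


def _beta(net: NeuronalNetwork) -> np.ndarray:
    if callable(net.vthE):
        raise ValueError("function-valued excitatory thresholds: supply their maximum "
                         "explicitly by building a network with constant thresholds")
    return net.vthE


def threshold_premise(net: NeuronalNetwork, part: PartitionedNetwork,
                      S0I, order: str = "first", Sdot0I=None) -> ConditionReport:
    """Evaluate the threshold premise ``vth_tilde <= -Btilde w`` elementwise.

    ``w`` bounds the uninhibited inhibitory drives from below by comparison
    with their decoupled dynamics: each stays above
    ``min(S_i(0), tau_i * eta_i)`` (first order), with the derivative-aware
    ``alpha_i`` replacing ``eta_i`` for the Erlang-kernel model.
    """
    S0I = np.asarray(S0I, dtype=float)
    if S0I.shape != (net.nI,):
        raise ValueError(f"S0I must have length {net.nI}")
    eta = _eta(net, part)
    tau2 = np.diag(np.linalg.inv(part.L2I))
    S20 = S0I[part.no_input_set]
    alpha = None
    if order == "second":
        if Sdot0I is None:
            raise ValueError("the second-order premise needs initial derivatives Sdot0I")
        Sdot0I = np.asarray(Sdot0I, dtype=float)
        u0 = Sdot0I[part.no_input_set] + S20 / tau2
        alpha = np.minimum(u0, tau2 * eta)
        w = np.minimum(S20, tau2 * alpha)
    elif order == "first":
        w = np.minimum(S20, tau2 * eta)
    else:
        raise ValueError("order must be 'first' or 'second'")

    if callable(net.vthE) or callable(net.vthI):
        raise ValueError("threshold premise with function-valued thresholds is not "
                         "supported; supply constant bounds")
    vth_tilde = np.concatenate([net.vthE, net.vthI[part.permutation[:part.q]]])
    lhs = vth_tilde + part.Btilde @ w
    failing = [int(i) for i in np.nonzero(lhs > 0)[0]]
    holds = not failing
    return ConditionReport(holds=bool(holds),
                           premise_flags={"vth_leq_minus_Bw": bool(holds)},
                           lhs_vector=lhs, w=w, eta=eta, alpha=alpha,
                           failing_indices=failing)


def _require_satlin(net: NeuronalNetwork) -> None:
    if net.activation.kind != "saturating_linear":
        raise ValueError("the time-constant conditions assume the saturating-linear "
                         f"activation, got {net.activation.kind!r}")


def time_constant_condition_first_order(net: NeuronalNetwork, part: PartitionedNetwork,
                                        S0E, S0I,
                                        epsilon: float = DEFAULT_EPSILON) -> ConditionReport:
    """Inhibitory time-constant condition for the exponential-kernel model.

    When the thresholds of the uninhibited inhibitory subset are positive,
    their drives are large enough (small ``L2I``, i.e. prolonged time
    constants) that the inhibition delivered to every excitatory neuron
    outweighs the maximal recurrent excitation; all excitatory drives then
    converge to zero.  Requires ``A2EI`` rows to carry inhibition: a zero
    row makes the inequality unsatisfiable for that excitatory neuron.
    """
    _require_satlin(net)
    S0E = np.asarray(S0E, dtype=float)
    S0I = np.asarray(S0I, dtype=float)
    eta = _eta(net, part)
    fmax = net.activation.f_max
    ones2 = np.ones(part.L2I.shape[0])
    L2inv = np.linalg.inv(part.L2I)
    LEinv = np.linalg.inv(part.LE)
    floor2 = L2inv @ np.minimum(fmax * ones2, eta)

    premise_pos = bool(np.all(eta > STRICT_SLACK))
    S20 = S0I[part.no_input_set]
    premise_ic = bool(np.all(S20 - floor2 < -STRICT_SLACK))

    A2EI = net.AEI[:, part.no_input_set]
    beta = _beta(net)
    lhs = (net.AEE @ np.maximum(S0E, fmax * np.diag(LEinv))
           + A2EI @ (floor2 - epsilon * ones2) + beta)
    failing = [int(i) for i in np.nonzero(lhs > STRICT_SLACK)[0]]
    holds = premise_pos and premise_ic and not failing
    return ConditionReport(holds=bool(holds),
                           premise_flags={"vth2_positive": premise_pos,
                                          "initial_drive_below_floor": premise_ic,
                                          "inhibition_dominates": not failing},
                           lhs_vector=lhs, eta=eta, beta=beta, epsilon=epsilon,
                           failing_indices=failing)


def time_constant_condition_second_order(net: NeuronalNetwork, part: PartitionedNetwork,
                                         S0E, S0I, Sdot0E, Sdot0I,
                                         epsilon: float = DEFAULT_EPSILON) -> ConditionReport:
    """Inhibitory time-constant condition for the Erlang-kernel model.

    Same mechanism as the first-order condition, with the uninhibited
    drives bounded through the companion variable ``u = dS/dt + S/tau`` and
    an extra application of ``L2I^{-1}``, and with the excitatory upper
    bound accounting for initial derivatives.
    """
    _require_satlin(net)
    S0E, S0I = np.asarray(S0E, float), np.asarray(S0I, float)
    Sdot0E, Sdot0I = np.asarray(Sdot0E, float), np.asarray(Sdot0I, float)
    eta = _eta(net, part)
    fmax = net.activation.f_max
    ones2 = np.ones(part.L2I.shape[0])
    L2inv = np.linalg.inv(part.L2I)
    LEinv = np.linalg.inv(part.LE)
    floor1 = L2inv @ np.minimum(fmax * ones2, eta)

    premise_pos = bool(np.all(eta > STRICT_SLACK))
    S20 = S0I[part.no_input_set]
    Sd20 = Sdot0I[part.no_input_set]
    u0 = Sd20 + part.L2I @ S20
    premise_u = bool(np.all(u0 - floor1 < -STRICT_SLACK))
    floor2 = L2inv @ (floor1 - epsilon * ones2)
    premise_ic = bool(np.all(S20 - floor2 < -STRICT_SLACK))

    A2EI = net.AEI[:, part.no_input_set]
    beta = _beta(net)
    SE_bound = np.maximum(
        S0E, LEinv @ np.maximum(Sdot0E + part.LE @ S0E, fmax * np.diag(LEinv)))
    lhs = net.AEE @ SE_bound + A2EI @ (floor2 - epsilon * ones2) + beta
    failing = [int(i) for i in np.nonzero(lhs > STRICT_SLACK)[0]]
    holds = premise_pos and premise_u and premise_ic and not failing
    return ConditionReport(holds=bool(holds),
                           premise_flags={"vth2_positive": premise_pos,
                                          "companion_below_floor": premise_u,
                                          "initial_drive_below_floor": premise_ic,
                                          "inhibition_dominates": not failing},
                           lhs_vector=lhs, eta=eta, beta=beta, epsilon=epsilon,
                           failing_indices=failing)
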