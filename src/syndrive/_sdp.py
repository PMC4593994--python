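"""Internal semidefinite feasibility solver for the synchronization LMIs.

The certificate search

    maximize   min eig of { [[Q, -P], [-P, R]],  Omega(P, Q, R),  P,  R }
    over       P = P^T, Q = Q^T, R diagonal,

with ``Omega = P*Lop + Lop^T*P - Q - At^T R At`` affine in the variables, is
a concave nonsmooth maximization.  It is solved by annealed softmin
smoothing: the spectral softmin ``F_mu = -mu * log tr exp(-M/mu)`` (shifted
for overflow safety) is smooth and concave with gradient given by the matrix
Gibbs weights, so L-BFGS converges quickly at each smoothing level.  A
quadratic penalty pins the overall scale, which is otherwise free because
the objective is positively homogeneous.  Problem sizes here are tiny
(n <= 24), so dense eigendecompositions dominate and a solve takes well
under a second.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize


def _softmin_weights(mats: list[np.ndarray], mu: float):
    """Shifted spectral softmin over a list of symmetric matrices.

    Returns the softmin value and the Gibbs-weight matrix for each input
    (weights sum to one in trace).
    """
    eigs = [eigh(M) for M in mats]
    shift = min(w.min() for w, _ in eigs)
    Ws, Z = [], 0.0
    for w, V in eigs:
        e = np.exp(-(w - shift) / mu)
        Ws.append((V * e) @ V.T)
        Z += e.sum()
    return shift - mu * np.log(Z), [W / Z for W in Ws]


def solve_sync_lmi(At: np.ndarray, Lop: np.ndarray,
                   mu_schedule=(1.0, 0.3, 0.1, 0.03, 0.01),
                   maxiter: int = 600) -> dict:
    """Search P, Q (symmetric), R (diagonal) maximizing the joint LMI margin.

    ``Lop`` is the linear decay operator entering ``Omega`` as
    ``P Lop + Lop^T P``; it need not be symmetric (the second-order
    companion form is not).
    """
    At = np.asarray(At, dtype=float)
    Lop = np.asarray(Lop, dtype=float)
    n = At.shape[0]
    s0 = 3.0 * n * max(1.0, np.trace(Lop) / n)
    iu = np.triu_indices(n)
    m_iu = iu[0].size
    rho = 10.0
    diag_mask = np.equal(iu[0], iu[1])

    def unpack(x):
        P = np.zeros((n, n)); P[iu] = x[:m_iu]
        P = P + P.T - np.diag(np.diag(P))
        Q = np.zeros((n, n)); Q[iu] = x[m_iu:2 * m_iu]
        Q = Q + Q.T - np.diag(np.diag(Q))
        return P, Q, x[2 * m_iu:]

    def symg(G):
        out = (G + G.T)[iu].copy()
        out[diag_mask] /= 2.0
        return out

    def negJ(x, mu):
        P, Q, r = unpack(x)
        R = np.diag(r)
        blk = np.block([[Q, -P], [-P, R]])
        Om = P @ Lop + Lop.T @ P - Q - At.T @ R @ At
        F, (Wb, Wo, Wp, Wr) = _softmin_weights([blk, Om, P, R], mu)
        W11, W12, W22 = Wb[:n, :n], Wb[:n, n:], Wb[n:, n:]
        GP = -(W12 + W12.T) + (Lop @ Wo + Wo @ Lop.T) + Wp
        GQ = W11 - Wo
        gr = np.diag(W22) - np.diag(At @ Wo @ At.T) + np.diag(Wr)
        s = np.trace(P) + np.trace(Q) + r.sum()
        pen = -2.0 * rho * (s / s0 - 1.0) / s0
        J = F - rho * (s / s0 - 1.0) ** 2
        g = np.concatenate([symg(GP + pen * np.eye(n)),
                            symg(GQ + pen * np.eye(n)), gr + pen])
        return -J, -g

    scale = s0 / (3 * n)
    x = np.concatenate([np.eye(n)[iu], np.eye(n)[iu], np.ones(n)]) * scale
    status = "converged"
    for mu in mu_schedule:
        res = minimize(negJ, x, args=(mu,), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        x = res.x
        if not res.success and "ABNORMAL" in str(res.message):
            status = f"lbfgs: {res.message}"
    P, Q, r = unpack(x)
    return {"P": P, "Q": Q, "R": np.diag(r), "status": status}
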