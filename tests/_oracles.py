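"""Independent oracles used by the test-suite.

Each oracle is deliberately implemented with a different method than the
code path it checks: generic constrained optimisation for the intersection
projection, the classical soft-threshold-and-normalise block update for the
penalty-free model, brute-force pair enumeration for the concordance index,
and an established survival library for the cumulative hazard.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def project_intersection_qcqp(v: np.ndarray, s: float, l2_radius: float = 1.0
                              ) -> np.ndarray:
    """Euclidean projection onto {||x||_1 <= s} intersect {||x||_2 <= r}
    via a generic solver.

    The l1 constraint is smoothed by the positive/negative split
    x = xp - xm, xp, xm >= 0, sum(xp + xm) <= s, turning the problem into
    a smooth QCQP that SLSQP handles.
    """
    v = np.asarray(v, dtype=float)
    p = len(v)

    def obj(z):
        x = z[:p] - z[p:]
        return float(np.sum((x - v) ** 2))

    def obj_grad(z):
        x = z[:p] - z[p:]
        g = 2.0 * (x - v)
        return np.concatenate([g, -g])

    cons = [
        {"type": "ineq", "fun": lambda z: s - np.sum(z),
         "jac": lambda z: -np.ones(2 * p)},
        {"type": "ineq",
         "fun": lambda z: l2_radius ** 2 - np.sum((z[:p] - z[p:]) ** 2),
         "jac": lambda z: np.concatenate([-2 * (z[:p] - z[p:]),
                                          2 * (z[:p] - z[p:])])},
    ]
    z0 = np.concatenate([np.clip(v, 0, None), np.clip(-v, 0, None)])
    nrm1, nrm2 = np.abs(v).sum(), np.linalg.norm(v)
    shrink = min(1.0, s / max(nrm1, 1e-12), l2_radius / max(nrm2, 1e-12))
    z0 = z0 * shrink * 0.999
    res = minimize(obj, z0, jac=obj_grad, method="SLSQP", constraints=cons,
                   bounds=[(0, None)] * (2 * p),
                   options={"maxiter": 500, "ftol": 1e-14})
    return res.x[:p] - res.x[p:]


def sgcca_block_update(blocks_X, design_c, s_values, w_init, max_iter=500,
                       tol=1e-10):
    """Classical plain-SGCCA solver: cyclic closed-form block updates.

    Each block maximises a linear function over the l1/l2 constraint set:
    w_j = S(z, lam) / ||S(z, lam)||_2 with z = X_j' sum_k c_jk X_k w_k and
    lam found by bisection so that the l1 norm of the normalised vector
    equals s_j (lam = 0 when already feasible).
    """

    def soft(z, lam):
        return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)

    def linear_max(z, s):
        nrm = np.linalg.norm(z)
        if nrm == 0:
            return np.zeros_like(z)
        w = z / nrm
        if np.abs(w).sum() <= s + 1e-12:
            return w
        lo, hi = 0.0, np.max(np.abs(z))
        for _ in range(200):
            lam = (lo + hi) / 2.0
            sz = soft(z, lam)
            nrm = np.linalg.norm(sz)
            if nrm == 0:
                hi = lam
                continue
            l1 = np.abs(sz).sum() / nrm
            if l1 > s:
                lo = lam
            else:
                hi = lam
        sz = soft(z, (lo + hi) / 2.0)
        return sz / np.linalg.norm(sz)

    J = len(blocks_X)
    n = blocks_X[0].shape[0]
    ws = [w.copy() for w in w_init]
    for _ in range(max_iter):
        delta = 0.0
        for j in range(J):
            z = np.zeros(n)
            for k in range(J):
                if k != j and design_c[j, k]:
                    z += design_c[j, k] * (blocks_X[k] @ ws[k])
            znew = blocks_X[j].T @ z
            wnew = linear_max(znew, s_values[j])
            delta = max(delta, np.linalg.norm(wnew - ws[j]))
            ws[j] = wnew
        if delta < tol:
            break
    return ws


def cindex_brute(risk, time, event):
    """Harrell's c by explicit double loop over all ordered pairs."""
    conc = 0.0
    n_comp = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if event[i] == 1 and time[i] < time[j]:
                n_comp += 1
                if risk[i] > risk[j]:
                    conc += 1.0
                elif risk[i] == risk[j]:
                    conc += 0.5
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return conc / n_comp


def nelson_aalen_lifelines(time, event):
    """Cumulative hazard at each subject's own time, from lifelines
    (Breslow-style tie handling, no small-sample smoothing)."""
    from lifelines import NelsonAalenFitter

    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(time, event_observed=event)
    ch = naf.cumulative_hazard_at_times(time)
    return np.asarray(ch, dtype=float)


def deviance_residuals_oracle(time, event):
    """Null-model deviance residuals built on the lifelines hazard."""
    lam = nelson_aalen_lifelines(time, event)
    delta = np.asarray(event, dtype=float)
    m = delta - lam
    inner = np.where(delta > 0, delta * np.log(np.maximum(delta - m, 1e-300)), 0.0)
    return np.sign(m) * np.sqrt(np.maximum(-2.0 * (m + inner), 0.0))
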