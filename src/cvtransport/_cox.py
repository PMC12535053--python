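"""Lightweight Cox proportional-hazards engine.

A small, vectorized Newton–Raphson fitter for the Cox partial likelihood
with case weights and Breslow tie handling, plus the Breslow baseline
cumulative-hazard estimator and survival prediction. It exists for the
inner loops that refit thousands of small Cox models (subgroup-tree split
search, bootstrap resampling of absolute risk reductions), where a full
modelling framework would dominate the runtime. Simulated event times are
continuous, so ties are rare and the Breslow approximation is innocuous
here; user-facing effect estimates go through lifelines (Efron ties,
robust variance) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CoxConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


def _risk_index(time_desc: np.ndarray) -> np.ndarray:
    """For times sorted descending, index of the last entry tied with each.

    ``cumsum(x)[_risk_index(t)][i]`` is then the sum of ``x`` over the risk
    set {j : t_j >= t_i}.
    """
    u = -time_desc  # ascending
    return np.searchsorted(u, u, side="right") - 1


def cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted Breslow log partial likelihood at `beta`."""
    w = np.ones(len(time)) if weights is None else weights
    order = np.argsort(-time, kind="stable")
    t, d, w, Xs = time[order], event[order], w[order], X[order]
    lp = Xs @ beta
    lp_c = lp - lp.max()
    s0 = np.cumsum(w * np.exp(lp_c))[_risk_index(t)]
    ev = d == 1
    return float(np.sum(w[ev] * (lp_c[ev] - np.log(s0[ev]))))


@dataclass
class CoxFit:
    beta: np.ndarray
    cov: np.ndarray  # inverse observed information
    loglik: float
    n: int
    n_events: int
    baseline_times: np.ndarray  # event times (ascending)
    baseline_dH: np.ndarray  # Breslow increments of H0 at those times

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def cumulative_hazard(self, t: float | np.ndarray) -> np.ndarray:
        """Baseline cumulative hazard H0(t) (step function, Breslow)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        csum = np.concatenate([[0.0], np.cumsum(self.baseline_dH)])
        idx = np.searchsorted(self.baseline_times, t, side="right")
        return csum[idx]

    def predict_survival(self, X: np.ndarray, t: float) -> np.ndarray:
        """S(t | x) = exp(-H0(t) * exp(x'beta)) for each row of X."""
        h0 = float(self.cumulative_hazard(t)[0])
        return np.exp(-h0 * np.exp(np.asarray(X, dtype=float) @ self.beta))


def cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    init: np.ndarray | None = None,
) -> CoxFit:
    """Newton–Raphson maximizer of the weighted Breslow partial likelihood."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if event.sum() == 0:
        raise CoxConvergenceError("no events in the data")

    order = np.argsort(-time, kind="stable")
    t, d, ws, Xs = time[order], event[order], w[order], X[order]
    ridx = _risk_index(t)
    ev = d == 1
    wev = ws[ev]

    # center covariates for numerical stability (shifts absorbed in baseline)
    xm = np.average(Xs, axis=0, weights=ws)
    Xc = Xs - xm

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    trace: list[float] = []

    def _ll_grad_hess(b):
        lp = Xc @ b
        lp_c = lp - lp.max()
        r = ws * np.exp(lp_c)
        s0 = np.cumsum(r)[ridx]
        s1 = np.cumsum(r[:, None] * Xc, axis=0)[ridx]
        ll = np.sum(wev * (lp_c[ev] - np.log(s0[ev])))
        xbar = s1[ev] / s0[ev, None]
        grad = (wev[:, None] * (Xc[ev] - xbar)).sum(axis=0)
        # second moment of the risk sets, packed into the symmetric upper
        # triangle and accumulated in chunks: O(chunk * p^2/2) memory
        iu, ju = np.triu_indices(p)
        q = len(iu)
        info_packed = np.zeros(q)
        ev_cum = np.cumsum(ev).astype(int)
        chunk = max(1, int(4e7 // max(q, 1)))
        carry = np.zeros(q)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            rx = Xc[start:stop] * r[start:stop, None]
            packed = rx[:, iu] * Xc[start:stop, ju]
            cs = carry + np.cumsum(packed, axis=0)
            carry = cs[-1]
            in_chunk = (ridx >= start) & (ridx < stop) & ev
            if in_chunk.any():
                s2_ev = cs[ridx[in_chunk] - start]
                xb = xbar[ev_cum[in_chunk] - 1]
                w_e = ws[in_chunk]
                info_packed += (
                    w_e[:, None] * (s2_ev / s0[in_chunk, None] - xb[:, iu] * xb[:, ju])
                ).sum(axis=0)
        info = np.zeros((p, p))
        info[iu, ju] = info_packed
        info[ju, iu] = info_packed
        return ll, grad, info

    ll, grad, info = _ll_grad_hess(beta)
    for _ in range(max_iter):
        trace.append(ll)
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}", trace)
        if np.linalg.norm(step) < 1e-12 * (1 + np.linalg.norm(beta)):
            break
        # step-halving line search; tolerance relative to |ll| to absorb
        # floating-point noise at convergence
        slack = 1e-10 * (1 + abs(ll))
        for _ in range(30):
            new_beta = beta + step
            new_ll = cox_loglik(new_beta, Xc, t, d, ws)
            if np.isfinite(new_ll) and new_ll >= ll - slack:
                break
            step = step / 2
        else:
            raise CoxConvergenceError("line search failed", trace)
        improved = new_ll - ll
        beta = new_beta
        ll, grad, info = _ll_grad_hess(beta)
        if abs(improved) < tol and np.linalg.norm(grad) < 1e-6 * max(1, abs(ll)):
            break
    else:
        if np.linalg.norm(grad) > 1e-3:
            raise CoxConvergenceError(
                f"Newton did not converge in {max_iter} iterations", trace
            )

    cov = np.linalg.inv(info + 1e-12 * np.eye(p))

    # Breslow baseline on the original (uncentered) covariate scale:
    # H0 increments dH(t_j) = sum of event weights at t_j / S0(t_j)
    lp = Xc @ beta
    r = ws * np.exp(lp)
    s0 = np.cumsum(r)[ridx]
    ev_times = t[ev]
    dH_num = ws[ev]
    dH = dH_num / s0[ev]
    # aggregate ties and sort ascending
    uniq, inv = np.unique(ev_times, return_inverse=True)
    dH_agg = np.zeros(len(uniq))
    np.add.at(dH_agg, inv, dH)
    # shift baseline back to uncentered covariates
    dH_agg = dH_agg * np.exp(-(xm @ beta))

    return CoxFit(
        beta=beta,
        cov=cov,
        loglik=float(ll),
        n=n,
        n_events=int(d.sum()),
        baseline_times=uniq,
        baseline_dH=dH_agg,
    )
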