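"""Cross-frequency phase fitting (XPF).

Given a narrowband reference ``r(t)`` at frequency f1 and multichannel
narrowband signals ``m_i(t)`` at f2, with f1:f2 = p:q, XPF finds real
weights ``w`` such that the component ``s = sum_i w_i m_i`` is in p:q phase
synchrony with the reference.  It minimizes, over real ``w``,

    sum_t | (sum_i w_i m~_i(t))^p  -  r~^[q](t) |^2 ,

where ``~`` denotes the analytic signal and ``r~^[q]`` is the reference
frequency-warped by q (phase multiplied, amplitude preserved).  The q-warp
rather than the plain q-th power keeps the target's magnitude on the scale
of the reference amplitude.  The complex residual is stacked as real and
imaginary parts, giving an ordinary real nonlinear least-squares problem;
for p = 1 it is linear and solved directly.

The objective is multimodal for p > 1, so the solver restarts from several
random initial weight vectors and keeps the best.  A phase-offset scan
(``K`` offsets of the warped reference on the unit circle) extends the
search from strict phase synchrony to phase locking with an arbitrary
constant phase lag.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .signal_core import FrequencyRatio, analytic, cf_plv, edge_slice, freq_warp_offset

__all__ = ["XPF", "fit_xpf", "fit_xpf_phase_locked"]


def _objective(u_pow: np.ndarray, target: np.ndarray) -> float:
    d = u_pow - target
    return float(np.sum(d.real**2 + d.imag**2))


def _solve_restart(M: np.ndarray, target: np.ndarray, p: int, w0: np.ndarray, tol: float, max_iter: int):
    """One descent from w0.  Returns (w, objective, converged, history)."""
    T, n = M.shape
    t_ri = np.concatenate([target.real, target.imag])
    history: list[float] = []

    if p == 1:
        # linear case: global optimum in closed form
        A = np.vstack([M.real, M.imag])
        w, *_ = np.linalg.lstsq(A, t_ri, rcond=None)
        obj = _objective(M @ w, target)
        return w, obj, True, [obj]

    def residual(w):
        u = M @ w
        d = u**p - target
        return np.concatenate([d.real, d.imag])

    def jac(w):
        u = M @ w
        # jac is evaluated at accepted iterates only -> monotone history
        history.append(_objective(u**p, target))
        Jc = (p * u ** (p - 1))[:, None] * M
        return np.vstack([Jc.real, Jc.imag])

    res = least_squares(
        residual,
        w0,
        jac=jac,
        method="trf",
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter,
    )
    obj = _objective((M @ res.x) ** p, target)
    history.append(obj)
    return res.x, obj, bool(res.status > 0), history


class XPF(BaseEstimator):
    """Spatial-filter estimator for p:q cross-frequency phase synchrony.

    Parameters
    ----------
    ratio : tuple (p, q) or FrequencyRatio
        Frequency ratio f1:f2 of reference to fit band.
    K : int
        Number of phase offsets scanned (1 = strict synchrony; ~10 to
        search for locking with an arbitrary constant phase lag).
    n_restarts : int
        Random initializations per phase offset (the objective is
        multimodal for p > 1; ignored for p = 1, which is solved exactly).
    edge_margin_s : float
        Seconds discarded at each end before building residuals and phases.
    fs : float
        Sampling rate (Hz), used only to convert the edge margin.
    tol, max_iter : float, int
        Solver tolerances (ftol = xtol = gtol) and residual-evaluation cap
        per restart.
    prescale : bool
        Scale fit channels and warped reference to unit mean power before
        optimizing (weights are returned on the original scale).
    random_state : int, Generator or None
        Seeds the restart draws.

    Attributes
    ----------
    weights_ : ndarray (n_channels,)
        Fitted spatial filter, original channel scale.
    component_ : ndarray (n_samples,)
        ``X @ weights_`` (full length, edges included).
    plv_ : float
        Cross-frequency PLV between reference and component phases at p:q,
        measured on interior samples.
    objective_ : float
        Residual sum of squares at the optimum (pre-scaled space).
    converged_ : bool
    restarts_used_ : int
    offset_k_ : int
        Winning phase-offset index (0 when K = 1).
    objective_history_ : list of float
        Objective at each accepted solver iterate of the winning restart
        (non-increasing).
    """

    def __init__(
        self,
        ratio=(1, 2),
        K: int = 1,
        n_restarts: int = 10,
        edge_margin_s: float = 1.0,
        fs: float = 200.0,
        tol: float = 1e-10,
        max_iter: int = 500,
        prescale: bool = True,
        random_state=None,
    ):
        self.ratio = ratio
        self.K = K
        self.n_restarts = n_restarts
        self.edge_margin_s = edge_margin_s
        self.fs = fs
        self.tol = tol
        self.max_iter = max_iter
        self.prescale = prescale
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "XPF":
        """Fit the filter on ``X`` (n_samples, n_channels) narrowband
        fit-band data against reference ``y`` (n_samples,) at f1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.size > 1:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError(f"length mismatch: X has {X.shape[0]} samples, reference {y.shape[0]}")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in inputs")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        ratio = FrequencyRatio.coerce(self.ratio)
        p, q = ratio.p, ratio.q
        rng = np.random.default_rng(self.random_state)

        Mz = analytic(X)
        rz = analytic(y)
        keep = edge_slice(X.shape[0], self.fs, self.edge_margin_s)
        M = Mz[keep]
        r = rz[keep]

        if self.prescale:
            ch_scale = np.sqrt(np.mean(np.abs(M) ** 2, axis=0))
            ch_scale[ch_scale == 0] = 1.0
        else:
            ch_scale = np.ones(M.shape[1])
        Ms = M / ch_scale

        best = None  # (plv, -obj) maximized
        n_restarts = 1 if p == 1 else int(self.n_restarts)
        for k in range(self.K):
            target = freq_warp_offset(r, q, k, self.K)
            if self.prescale:
                tscale = np.sqrt(np.mean(np.abs(target) ** 2))
                if tscale > 0:
                    target = target / tscale
            # common seeded restart pool per offset
            inits = rng.standard_normal((n_restarts, Ms.shape[1]))
            k_best = None
            for j in range(n_restarts):
                w0 = inits[j]
                u0 = Ms @ w0
                rms = np.sqrt(np.mean(np.abs(u0) ** 2))
                if rms > 0:
                    w0 = w0 / rms
                w, obj, conv, hist = _solve_restart(Ms, target, p, w0, self.tol, self.max_iter)
                if k_best is None or obj < k_best[1] - 1e-12:
                    k_best = (w, obj, conv, hist, j)
            w, obj, conv, hist, j = k_best
            comp_phase = np.angle(Ms @ w)
            plv = cf_plv(np.angle(r), comp_phase, ratio)
            cand = (plv, -obj, k, w, conv, hist, j)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand

        plv, neg_obj, k_win, w_scaled, conv, hist, j_win = best
        weights = w_scaled / ch_scale
        self.ratio_ = ratio
        self.weights_ = weights
        self.component_ = X @ weights
        self.plv_ = float(plv)
        self.objective_ = float(-neg_obj)
        self.converged_ = bool(conv)
        self.restarts_used_ = n_restarts * self.K
        self.offset_k_ = int(k_win)
        self.objective_history_ = hist
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Apply the fitted spatial filter: component time course of ``X``."""
        check_is_fitted(self, "weights_")
        return np.asarray(X, dtype=float) @ self.weights_


def fit_xpf(
    reference: np.ndarray,
    fit_signals: np.ndarray,
    ratio,
    fs: float = 200.0,
    n_restarts: int = 10,
    edge_margin_s: float = 1.0,
    random_state=None,
    **kwargs,
) -> XPF:
    """Functional wrapper around :class:`XPF` with K = 1 (strict synchrony)."""
    est = XPF(
        ratio=ratio,
        K=1,
        n_restarts=n_restarts,
        edge_margin_s=edge_margin_s,
        fs=fs,
        random_state=random_state,
        **kwargs,
    )
    return est.fit(fit_signals, reference)


def fit_xpf_phase_locked(
    reference: np.ndarray,
    fit_signals: np.ndarray,
    ratio,
    K: int,
    fs: float = 200.0,
    n_restarts: int = 10,
    edge_margin_s: float = 1.0,
    random_state=None,
    **kwargs,
) -> XPF:
    """Phase-offset scan: runs the fit once per offset k = 0..K-1 of the
    warped reference and keeps the run with the highest PLV."""
    est = XPF(
        ratio=ratio,
        K=K,
        n_restarts=n_restarts,
        edge_margin_s=edge_margin_s,
        fs=fs,
        random_state=random_state,
        **kwargs,
    )
    return est.fit(fit_signals, reference)
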