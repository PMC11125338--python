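"""Convex decomposition of skin conductance into phasic and tonic parts.

The raw galvanic skin response y is modelled as

    y = r + t + e,    r = K p,    p >= 0,

where p is a sparse non-negative driver of sudomotor-nerve activity, K the
discrete convolution with a biexponential (Bateman) skin conductance response
kernel, t a smooth tonic component (piecewise-linear spline plus linear
drift) and e a Gaussian residual.  The components solve the convex program

    minimize  1/2 ||y - Kp - Bq - Cd||^2 + alpha ||p||_1 + gamma/2 ||q||^2
    subject to p >= 0

with B the spline basis, C = [1, t] the drift and q, d free.  Because p is
non-negative the l1 term is linear, so after eliminating the free tonic
block analytically the problem reduces to a non-negative quadratic program
min_p>=0 1/2 p'Hp - c'p, solved exactly by a Lawson-Hanson style active-set
iteration; the Karush-Kuhn-Tucker residual is reported in the solver
diagnostics.  The dense convolution-matrix formulation is adequate for
records up to a few minutes at 4 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .errors import ConfigError, SolverError
from .recording import Channel

logger = logging.getLogger("tostab.eda")


@dataclass(frozen=True)
class BatemanParams:
    """Biexponential SCR kernel time constants (seconds)."""

    tau_rise: float = 0.7
    tau_decay: float = 2.0

    def validate(self) -> None:
        if not (0 < self.tau_rise < self.tau_decay):
            raise ConfigError("Bateman kernel requires 0 < tau_rise < tau_decay")

    def peak_time(self) -> float:
        """Analytic mode of the kernel."""
        r, d = self.tau_rise, self.tau_decay
        return float(np.log(d / r) * d * r / (d - r))


def bateman_kernel(
    params: BatemanParams, rate: float, support: float | None = None
) -> np.ndarray:
    """Sampled kernel k(t) = exp(-t/tau_decay) - exp(-t/tau_rise), t >= 0,
    normalized to unit peak.  The default support extends until the tail
    falls below 1e-6 of the peak."""
    params.validate()
    if rate <= 0:
        raise ConfigError("rate must be > 0")
    if support is None:
        # tail is dominated by the slow exponential
        peak = np.exp(-params.peak_time() / params.tau_decay)
        support = params.tau_decay * (np.log(1e6) + np.log(peak) * -1.0) + params.peak_time()
    t = np.arange(0.0, support, 1.0 / rate)
    k = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ConfigError("degenerate kernel")
    return k / peak


@dataclass
class EdaDecomposition:
    """Result of the convex decomposition; y = phasic + tonic + residual
    holds identically by construction."""

    time: np.ndarray
    raw: np.ndarray
    phasic: np.ndarray
    tonic: np.ndarray
    driver: np.ndarray
    residual: np.ndarray
    objective: float
    diagnostics: dict

    def window_mean_phasic(self, start: float, stop: float) -> float:
        """Mean phasic level on [start, stop); NaN when no samples fall in
        the window.  Negative means (solver tolerance) are clipped at 0."""
        sel = (self.time >= start) & (self.time < stop)
        if not sel.any():
            return float("nan")
        m = float(self.phasic[sel].mean())
        if m < 0:
            logger.debug("clipped negative phasic window mean %.3g", m)
        return max(m, 0.0)


def _tonic_basis(t: np.ndarray, knot_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear hat functions on equally spaced knots, plus an
    unpenalized linear-drift pair [1, t]."""
    t0, t1 = t[0], t[-1]
    n_knots = max(int(np.ceil((t1 - t0) / knot_spacing)) + 1, 2)
    knots = np.linspace(t0, t1, n_knots)
    B = np.zeros((len(t), n_knots))
    for j, kj in enumerate(knots):
        left = knots[j - 1] if j > 0 else kj - 1.0
        right = knots[j + 1] if j + 1 < n_knots else kj + 1.0
        B[:, j] = np.clip(
            np.where(t <= kj, (t - left) / (kj - left), (right - t) / (right - kj)),
            0.0, None,
        )
    C = np.column_stack([np.ones_like(t), t - t0])
    return B, C


def decompose_eda(
    sc: np.ndarray,
    rate: float = 4.0,
    params: BatemanParams | None = None,
    alpha: float = 8e-4,
    gamma: float = 1e-2,
    knot_spacing: float = 10.0,
    time: np.ndarray | None = None,
    max_iter: int = 2000,
) -> EdaDecomposition:
    """Decompose a finite skin-conductance series into phasic, tonic and
    residual components.

    The record should be long enough for the tonic model to be identifiable
    (roughly 30 s or more); NaNs must be handled upstream (mask short gaps by
    interpolation, split at long ones -- see :func:`decompose_recording`).
    """
    y = np.asarray(sc, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise ConfigError("sc must be a 1-D series with at least 8 samples")
    if not np.isfinite(y).all():
        raise ConfigError("sc contains non-finite values; interpolate or split upstream")
    params = params or BatemanParams()
    params.validate()
    n = y.size
    t = np.arange(n) / rate if time is None else np.asarray(time, dtype=float)

    # impulse response: the kernel's leading zero sample is dropped so an
    # impulse at sample i starts acting at sample i and the convolution
    # matrix has a positive diagonal (invertible)
    kern = bateman_kernel(params, rate)
    if kern[0] == 0.0 and kern.size > 1:
        kern = kern[1:]
    col = np.zeros(n)
    m = min(n, kern.size)
    col[:m] = kern[:m]
    K = toeplitz(col, np.zeros(n))
    B, C = _tonic_basis(t, knot_spacing)
    nb = B.shape[1]
    Bf = np.hstack([B, C])
    M = Bf.T @ Bf
    M[np.arange(nb), np.arange(nb)] += gamma

    # partial minimization over the free tonic block: residual metric
    # Q = I - Bf M^{-1} Bf', reduced problem min_{p>=0} 1/2 p'Hp - c'p
    Minv_BfT = np.linalg.solve(M, Bf.T)
    QK = K - Bf @ (Minv_BfT @ K)
    Qy = y - Bf @ (Minv_BfT @ y)
    H = K.T @ QK
    c = K.T @ Qy - alpha
    H[np.arange(n), np.arange(n)] += 1e-10 * max(np.trace(H) / n, 1e-30)

    p, n_iter = _nn_quadprog(H, c, max_iter=max_iter)

    grad = H @ p - c
    active = p <= 0
    kkt = max(
        float(np.abs(grad[~active]).max(initial=0.0)),
        float(np.clip(-grad[active], 0.0, None).max(initial=0.0)),
    )
    scale = max(float(np.abs(c).max()), 1.0)
    if kkt > 1e-6 * scale:
        raise SolverError(f"decomposition did not converge (KKT {kkt:.2e})")

    u = Minv_BfT @ (y - K @ p)
    q, d = u[:nb], u[nb:]
    phasic = K @ p
    tonic = Bf @ u
    resid = y - phasic - tonic
    objective = (0.5 * resid @ resid + alpha * p.sum()
                 + 0.5 * gamma * q @ q)
    return EdaDecomposition(
        time=t,
        raw=y,
        phasic=phasic,
        tonic=tonic,
        driver=p,
        residual=resid,
        objective=float(objective),
        diagnostics={
            "success": True,
            "n_iter": n_iter,
            "kkt_residual": kkt,
            "l1_driver": float(p.sum()),
        },
    )


def _nn_quadprog(H: np.ndarray, c: np.ndarray, max_iter: int = 2000,
                 tol_rel: float = 1e-12) -> tuple[np.ndarray, int]:
    """Exact active-set solution of min_{p >= 0} 1/2 p'Hp - c'p for SPD H
    (Lawson-Hanson pattern: grow the passive set by the most violated
    gradient coordinate, step back to the boundary when a passive
    coordinate would turn negative)."""
    n = H.shape[0]
    p = np.zeros(n)
    passive = np.zeros(n, dtype=bool)
    tol = tol_rel * max(float(np.abs(c).max()), 1e-30)
    n_iter = 0
    for _ in range(max_iter):
        n_iter += 1
        w = c - H @ p
        w_masked = np.where(passive, -np.inf, w)
        j = int(np.argmax(w_masked))
        if w_masked[j] <= tol:
            break
        passive[j] = True
        while True:
            idx = np.flatnonzero(passive)
            s = np.linalg.solve(H[np.ix_(idx, idx)], c[idx])
            if (s > 0).all():
                p[:] = 0.0
                p[idx] = s
                break
            # step toward s until the first passive coordinate hits zero
            pi = p[idx]
            neg = s <= 0
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(neg, pi / (pi - s), np.inf)
            alpha_step = float(ratios.min())
            pi_new = pi + alpha_step * (s - pi)
            pi_new[neg & (ratios <= alpha_step + 1e-15)] = 0.0
            p[:] = 0.0
            p[idx] = np.clip(pi_new, 0.0, None)
            passive[idx] = p[idx] > 0.0
            if not passive.any():
                break
    else:
        raise SolverError("active-set iteration limit reached")
    return p, n_iter


def decompose_recording(
    channel: Channel,
    rate: float = 4.0,
    max_gap: float = 2.0,
    **kwargs,
) -> EdaDecomposition:
    """Decompose a GSR channel that may contain masked samples.

    Gaps of at most ``max_gap`` seconds are linearly interpolated; longer
    gaps split the record into independently decomposed segments, stitched
    back with NaN components inside the gaps.
    """
    t, v = channel.time, channel.values.copy()
    miss = channel.missing.copy()
    if not miss.any():
        return decompose_eda(v, rate=rate, time=t, **kwargs)

    # identify runs of missing samples
    idx = np.flatnonzero(miss)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    long_runs = []
    for run in runs:
        gap = t[run[-1]] - t[run[0]] + 1.0 / rate
        if gap <= max_gap:
            v[run] = np.interp(t[run], t[~miss], v[~miss])
            miss[run] = False
        else:
            long_runs.append(run)
    if not long_runs:
        return decompose_eda(v, rate=rate, time=t, **kwargs)

    logger.info("GSR record split at %d long gap(s)", len(long_runs))
    out_phasic = np.full(len(t), np.nan)
    out_tonic = np.full(len(t), np.nan)
    out_driver = np.full(len(t), np.nan)
    objective = 0.0
    diagnostics = {"segments": []}
    cut = np.zeros(len(t), dtype=bool)
    for run in long_runs:
        cut[run] = True
    seg_ids = np.cumsum(np.r_[0, np.diff(cut.astype(int)) != 0])
    for sid in np.unique(seg_ids):
        sel = (seg_ids == sid) & ~cut
        if sel.sum() < 8:
            continue
        sub = decompose_eda(v[sel], rate=rate, time=t[sel], **kwargs)
        out_phasic[sel] = sub.phasic
        out_tonic[sel] = sub.tonic
        out_driver[sel] = sub.driver
        objective += sub.objective
        diagnostics["segments"].append(sub.diagnostics)
    return EdaDecomposition(
        time=t, raw=channel.values, phasic=out_phasic, tonic=out_tonic,
        driver=out_driver, residual=channel.values - out_phasic - out_tonic,
        objective=objective, diagnostics=diagnostics,
    )
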