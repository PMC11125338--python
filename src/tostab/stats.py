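"""Repeated-measures stabilization statistics.

For each variable the window features form a units x windows repeated-
measures matrix.  The unit of analysis is the individual takeover attempt
by default -- study-scale designs yield hundreds of attempts from a few
dozen drivers, and attempt-level units match the large denominator degrees
of freedom such analyses report -- with driver-level aggregation available
as an option.  The procedure is:

1. one-factor repeated-measures ANOVA over the k = 7 windows, with
   Mauchly's test of sphericity and the Greenhouse-Geisser correction of the
   degrees of freedom when sphericity is violated;
2. if the ANOVA rejects, two-sided paired t-tests for all k(k-1)/2 = 21
   window pairs with Bonferroni adjustment;
3. a variable counts as stabilized in the first window that shows no
   adjusted-significant difference against any subsequent window.  The last
   window has no subsequent windows and is therefore not a candidate: if no
   earlier window qualifies the variable is reported as not stabilized
   within the horizon.

Complete cases (listwise deletion) enter the ANOVA; the t-tests use
pairwise-complete data.  Window pairs with fewer than two complete pairs are
untestable and count as "no difference observed", with a caveat recorded in
the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (ConfigError, DegenerateDataError, InsufficientDataError)
from .features import WindowGrid, build_window_grid

logger = logging.getLogger("tostab.stats")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: float
    df2: float
    p: float                 # Greenhouse-Geisser corrected when applied
    p_uncorrected: float
    p_gg: float
    epsilon: float
    mauchly_w: float
    mauchly_p: float
    correction_applied: bool
    n_complete: int
    k: int


@dataclass(frozen=True)
class PairwiseTestMatrix:
    t: np.ndarray            # k x k, symmetric, NaN diagonal
    p_raw: np.ndarray
    p_adj: np.ndarray        # min(1, m * p_raw)
    n_pairs: np.ndarray
    significant: np.ndarray  # bool, p_adj < alpha
    untestable: np.ndarray   # bool, fewer than 2 complete pairs
    m: int                   # number of comparisons, k(k-1)/2
    alpha: float


@dataclass(frozen=True)
class StabilizationResult:
    variable: str
    window_length: float
    stabilized_at: float | None
    plateaus: tuple[tuple[float, float], ...]
    anova: AnovaResult
    tests: PairwiseTestMatrix | None
    n_total: int
    n_complete: int
    has_untestable_pairs: bool = False


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the contrast space (orthogonal to 1)."""
    helmert = np.zeros((k, k - 1))
    for j in range(k - 1):
        helmert[: j + 1, j] = 1.0
        helmert[j + 1, j] = -(j + 1.0)
    return helmert / np.linalg.norm(helmert, axis=0)


def mauchly_sphericity(matrix: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square approximation p-value.

    ``matrix`` is a complete n x k repeated-measures array with n > k.
    For k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    if k == 2:
        return 1.0, 1.0
    if n <= k:
        raise InsufficientDataError("Mauchly's test requires n > k")
    S = np.cov(X.T, ddof=1)
    C = _orthonormal_contrasts(k)
    Sc = C.T @ S @ C
    sign, logdet = np.linalg.slogdet(Sc)
    tr = np.trace(Sc)
    if sign <= 0 or not np.isfinite(logdet) or tr <= 0:
        raise DegenerateDataError("singular contrast covariance")
    log_w = logdet - (k - 1) * np.log(tr / (k - 1))
    w = float(np.exp(log_w))
    d = k - 1
    # Box's chi-square approximation with the second-order term
    corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1.0))
    omega2 = ((d + 2.0) * (d - 1.0) * (d - 2.0)
              * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
              / (288.0 * ((n - 1.0) * d * corr) ** 2))
    chi2 = -(n - 1.0) * corr * log_w
    df = k * (k - 1.0) / 2.0 - 1.0
    p1 = float(sps.chi2.sf(chi2, df))
    p2 = float(sps.chi2.sf(chi2, df + 4.0))
    p = min(max(p1 + omega2 * (p2 - p1), 0.0), 1.0) if df > 0 else 1.0
    return min(w, 1.0), p


def gg_epsilon(covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the k x k covariance of the repeated
    measures: the eigenvalue form (sum lambda)^2 / ((k-1) sum lambda^2) of
    the double-centered covariance, clipped to [1/(k-1), 1]."""
    S = np.asarray(covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ConfigError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ConfigError("covariance must be symmetric")
    k = S.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    S_c = J @ S @ J
    lam = np.linalg.eigvalsh(S_c)
    num = lam.sum() ** 2
    den = (k - 1) * (lam**2).sum()
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(matrix: np.ndarray, alpha: float = 0.05) -> AnovaResult:
    """One-factor within-subject ANOVA with sphericity handling.

    The Greenhouse-Geisser correction is applied when Mauchly's test rejects
    at ``alpha``; both the corrected and uncorrected p-values are reported.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ConfigError("matrix must be 2-D (units x windows)")
    if np.isnan(X).any():
        raise ConfigError("rm_anova requires complete cases")
    n, k = X.shape
    if n < 3:
        raise InsufficientDataError(f"need at least 3 complete units, got {n}")
    if k < 2:
        raise ConfigError("need at least 2 windows")

    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_factor = n * ((col_means - grand) ** 2).sum()
    ss_subject = k * ((row_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_error = ss_total - ss_factor - ss_subject
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - 1.0)

    scale = max(ss_total, 1e-300)
    if ss_factor / scale < 1e-14 or ss_error <= 0:
        f = 0.0 if ss_factor / scale < 1e-14 else float("inf")
        p = 1.0 if f == 0.0 else 0.0
        return AnovaResult(f, df1, df2, p, p, p, 1.0, float("nan"),
                           float("nan"), False, n, k)

    f = (ss_factor / df1) / (ss_error / df2)
    p_unc = float(sps.f.sf(f, df1, df2))
    eps = gg_epsilon(np.cov(X.T, ddof=1))
    p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
    try:
        w, w_p = mauchly_sphericity(X)
    except (DegenerateDataError, InsufficientDataError):
        w, w_p = float("nan"), float("nan")
    apply_gg = bool(np.isfinite(w_p) and w_p < alpha)
    return AnovaResult(
        f=float(f),
        df1=eps * df1 if apply_gg else df1,
        df2=eps * df2 if apply_gg else df2,
        p=p_gg if apply_gg else p_unc,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        epsilon=eps,
        mauchly_w=w,
        mauchly_p=w_p,
        correction_applied=apply_gg,
        n_complete=n,
        k=k,
    )


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-sided paired t on pairwise-complete rows; handles zero variance."""
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 2:
        return float("nan"), float("nan"), n
    d = x[ok] - y[ok]
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, n
        return float(np.sign(d.mean()) * np.inf), 0.0, n
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), p, n


def pairwise_paired_tests(matrix: np.ndarray, alpha: float = 0.05) -> PairwiseTestMatrix:
    """All-pairs paired t-tests with Bonferroni adjustment.

    ``matrix`` is n x k and may contain NaN; each pair uses its pairwise-
    complete rows.  Pairs with fewer than two complete pairs are flagged
    untestable and treated as showing no difference (caveat propagated)."""
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    m = k * (k - 1) // 2
    t = np.full((k, k), np.nan)
    p_raw = np.full((k, k), np.nan)
    p_adj = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    sig = np.zeros((k, k), dtype=bool)
    untestable = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            tij, pij, nij = _paired_t(X[:, i], X[:, j])
            n_pairs[i, j] = n_pairs[j, i] = nij
            if np.isnan(pij):
                untestable[i, j] = untestable[j, i] = True
                logger.warning(
                    "window pair (%d, %d) untestable (<2 complete pairs); "
                    "counted as no difference observed", i, j)
                continue
            t[i, j] = t[j, i] = tij
            p_raw[i, j] = p_raw[j, i] = pij
            adj = min(1.0, m * pij)
            p_adj[i, j] = p_adj[j, i] = adj
            sig[i, j] = sig[j, i] = adj < alpha
    return PairwiseTestMatrix(t, p_raw, p_adj, n_pairs, sig, untestable,
                              m=m, alpha=alpha)


# ---------------------------------------------------------------------------
# stabilization rule
# ---------------------------------------------------------------------------


def _plateaus(sig: np.ndarray, starts: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Maximal runs of consecutive windows (length >= 2) with no significant
    pair inside the run."""
    k = len(starts)
    runs = []
    a = 0
    while a < k - 1:
        b = a
        while b + 1 < k and not sig[a:b + 2, a:b + 2].any():
            b += 1
        if b > a:
            runs.append((float(starts[a]), float(starts[b])))
            a = b
        else:
            a += 1
    # drop runs contained in a longer one
    out = [r for r in runs
           if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    return tuple(out)


def stabilization_time(
    tests: PairwiseTestMatrix | None,
    grid: WindowGrid,
    anova: AnovaResult,
    variable: str = "",
    n_total: int | None = None,
    alpha: float | None = None,
) -> StabilizationResult:
    """Apply the stabilization criterion.

    When the overall ANOVA does not reject, no pairwise differences exist by
    the procedure's sequencing and the variable is stabilized from the first
    window.  Otherwise the first window with no adjusted-significant
    difference against all subsequent windows wins; the vacuous last window
    is not a candidate.  Transient plateaus (maximal runs without internal
    differences) are reported alongside, to describe dip-and-recover
    profiles."""
    starts = grid.starts
    k = len(starts)
    if alpha is None:
        alpha = tests.alpha if tests is not None else 0.05
    if anova.p >= alpha:
        full = ((float(starts[0]), float(starts[-1])),)
        return StabilizationResult(variable, grid.length, float(starts[0]),
                                   full, anova, tests, n_total or anova.n_complete,
                                   anova.n_complete)
    if tests is None:
        raise ConfigError("pairwise tests required when the ANOVA rejects")
    if tests.t.shape[0] != k:
        raise ConfigError("pairwise test matrix does not match the window grid")
    sig = tests.significant
    stabilized_at = None
    for i in range(k - 1):           # the last window is vacuous, not a candidate
        if not sig[i, i + 1:].any():
            stabilized_at = float(starts[i])
            break
    return StabilizationResult(
        variable, grid.length, stabilized_at, _plateaus(sig, starts), anova,
        tests, n_total or anova.n_complete, anova.n_complete,
        has_untestable_pairs=bool(tests.untestable.any()),
    )


# ---------------------------------------------------------------------------
# end-to-end per-variable analysis
# ---------------------------------------------------------------------------


def build_matrix(
    features: pd.DataFrame,
    variable: str,
    window_length: float,
    grid: WindowGrid,
    unit: str = "attempt",
) -> tuple[np.ndarray, list[str]]:
    """Pivot the long-form feature table into a units x windows matrix (NaN
    for missing cells).  ``unit='driver'`` averages attempts per driver."""
    sel = features[(features["variable"] == variable)
                   & (features["window_len_s"] == window_length)]
    if sel.empty:
        raise InsufficientDataError(
            f"feature table has no rows for variable '{variable}' "
            f"at window length {window_length}")
    index = "event_id" if unit == "attempt" else "driver_id"
    pivot = sel.pivot_table(index=index, columns="window_start_s",
                            values="value", aggfunc="mean", dropna=False)
    pivot = pivot.reindex(columns=grid.starts)
    return pivot.to_numpy(dtype=float), list(pivot.index)


def analyze_variable(
    features: pd.DataFrame,
    variable: str,
    window_length: float,
    alpha: float = 0.05,
    unit: str = "attempt",
    grid: WindowGrid | None = None,
) -> StabilizationResult:
    """Full procedure for one variable at one window length: assemble the
    repeated-measures matrix, test sphericity, run the ANOVA and (if it
    rejects) the Bonferroni-adjusted pairwise tests, then apply the
    stabilization rule."""
    if unit not in ("attempt", "driver"):
        raise ConfigError("unit must be 'attempt' or 'driver'")
    g = grid or build_window_grid(window_length)
    X, _units = build_matrix(features, variable, window_length, g, unit=unit)
    n_total = X.shape[0]
    complete = X[~np.isnan(X).any(axis=1)]
    n_complete = complete.shape[0]
    logger.info("%s (len %.0f s): %d units, %d complete cases",
                variable, window_length, n_total, n_complete)
    if n_complete < 3:
        raise InsufficientDataError(
            f"variable '{variable}': only {n_complete} complete cases")
    anova = rm_anova(complete, alpha=alpha)
    tests = pairwise_paired_tests(X, alpha=alpha) if anova.p < alpha else None
    return stabilization_time(tests, g, anova, variable=variable,
                              n_total=n_total, alpha=alpha)
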