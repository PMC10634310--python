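"""Structural identification, impulse responses, and MCMC diagnostics.

Identification is recursive: the reduced-form innovation covariance is
factored as Omega = A0 A0' with A0 lower triangular, so shocks to variables
earlier in the ordering may move later variables contemporaneously but not
vice versa.  Impulse responses propagate the identified impact vector through
the companion form of the lag polynomial; posterior uncertainty is summarized
pointwise by the median and the 16th/84th percentiles (a 68% band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import PosteriorDraws, lag_block
from .simulate import companion_matrix


@dataclass
class IRFSet:
    """Per-draw impulse responses to one identified shock.

    ``responses`` has shape (draws, variables, horizons+1); at horizon 0 the
    shock variable's own response equals ``shock_size`` by normalization.
    """

    shock_variable: str
    shock_size: float
    variable_order: tuple[str, ...]
    responses: np.ndarray


@dataclass
class IRFSummary:
    """Pointwise posterior median and 68% band of an impulse-response set."""

    shock_variable: str
    table: pd.DataFrame  # columns: shock, response, horizon, median, p16, p84


def cholesky_factor(omega: np.ndarray) -> np.ndarray:
    """Lower-triangular A0 with positive diagonal such that A0 A0' = Omega."""
    omega = np.asarray(omega, float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("Omega must be square")
    if not np.allclose(omega, omega.T, atol=1e-10 * max(1.0, np.abs(omega).max())):
        raise ValueError("Omega must be symmetric")
    try:
        return np.linalg.cholesky(0.5 * (omega + omega.T))
    except np.linalg.LinAlgError:
        raise ValueError("Omega is not positive definite") from None


def impulse_response(
    b: np.ndarray,
    a0: np.ndarray,
    shock_index: int,
    shock_size: float,
    horizons: int,
    n_vars: int,
    lag_order: int,
) -> np.ndarray:
    """Responses of all variables over horizons 0..H to one identified shock.

    The impact vector is A0's column for the shock, rescaled so the shock
    variable's horizon-0 response equals ``shock_size``; subsequent horizons
    propagate it through powers of the companion matrix.  Deterministic terms
    (fixed effects, trends) do not enter the propagation.
    """
    impact = a0[:, shock_index].astype(float)
    own = impact[shock_index]
    if own == 0:
        raise ValueError("impact normalization undefined: zero diagonal entry in A0")
    impact = impact * (shock_size / own)
    comp = companion_matrix(lag_block(b, n_vars, lag_order))
    state = np.zeros(comp.shape[0])
    state[:n_vars] = impact
    out = np.empty((n_vars, horizons + 1))
    out[:, 0] = impact
    for h in range(1, horizons + 1):
        state = comp @ state
        out[:, h] = state[:n_vars]
    return out


def stationarity_check(b: np.ndarray, n_vars: int, lag_order: int) -> float:
    """Spectral radius of the companion matrix built from B's lag block."""
    comp = companion_matrix(lag_block(b, n_vars, lag_order))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def compute_irfs(
    draws: PosteriorDraws,
    shock_variable: str,
    shock_size: float = 0.01,
    horizons: int = 10,
) -> IRFSet:
    """Posterior impulse responses: one Cholesky identification per draw."""
    order = draws.spec.variable_order
    if shock_variable not in order:
        raise ValueError(f"shock variable {shock_variable!r} not in ordering {order}")
    idx = order.index(shock_variable)
    m, p = draws.spec.n_vars, draws.spec.lag_order
    n = draws.n_retained
    responses = np.empty((n, m, horizons + 1))
    for d in range(n):
        a0 = cholesky_factor(draws.Omega_draws[d])
        responses[d] = impulse_response(draws.B_draws[d], a0, idx, shock_size, horizons, m, p)
    return IRFSet(shock_variable, shock_size, tuple(order), responses)


def summarize_irf(irfs: IRFSet) -> IRFSummary:
    """Median and 16th/84th percentiles of the responses, per cell."""
    if irfs.responses.shape[0] < 2:
        raise ValueError("need at least two draws to form a band")
    med = np.median(irfs.responses, axis=0)
    p16 = np.percentile(irfs.responses, 16, axis=0)
    p84 = np.percentile(irfs.responses, 84, axis=0)
    n_h = irfs.responses.shape[2]
    rows = []
    for v_idx, v in enumerate(irfs.variable_order):
        for h in range(n_h):
            rows.append((irfs.shock_variable, v, h, med[v_idx, h], p16[v_idx, h], p84[v_idx, h]))
    table = pd.DataFrame(rows, columns=["shock", "response", "horizon", "median", "p16", "p84"])
    return IRFSummary(irfs.shock_variable, table)


# -- convergence diagnostics ----------------------------------------------


def inefficiency_factor(chain: np.ndarray) -> float:
    """Inefficiency factor 1 + 2·sum_k w(k)·rho(k) of a scalar MCMC chain.

    Sample autocorrelations are tapered by a Parzen window with bandwidth
    4·(n/100)^0.25 and truncated at the first lag pair whose summed
    autocorrelation is nonpositive (the usual initial-positive-sequence
    guard).  An iid chain has factor ≈ 1; values slightly below 1 occur for
    negatively autocorrelated chains.
    """
    chain = np.asarray(chain, float).ravel()
    n = chain.size
    if n < 100:
        raise ValueError("chain too short (need ≥ 100 draws)")
    centered = chain - chain.mean()
    var = centered @ centered / n
    if var <= 1e-300 * max(1.0, chain.mean() ** 2):
        raise ValueError("constant chain has no inefficiency factor")
    bandwidth = 4.0 * (n / 100.0) ** 0.25
    max_lag = min(int(np.floor(bandwidth)), n - 1)
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = (centered[:-k] @ centered[k:]) / n / var
    # truncate at the first adjacent pair of autocorrelations summing ≤ 0
    cutoff = max_lag
    for k in range(1, max_lag):
        if acf[k] + acf[k + 1] <= 0:
            cutoff = k
            break
    total = 0.0
    for k in range(1, cutoff + 1):
        z = k / bandwidth
        if z <= 0.5:
            w = 1.0 - 6.0 * z**2 + 6.0 * z**3
        elif z <= 1.0:
            w = 2.0 * (1.0 - z) ** 3
        else:
            w = 0.0
        total += w * acf[k]
    return 1.0 + 2.0 * total


def convergence_report(draws: PosteriorDraws, include_deterministic: bool = False) -> dict:
    """Inefficiency factors for lag coefficients and covariance entries.

    Reports per-block min/max, the standard summary for judging whether the
    retained draws mix well (values near 1 mean nearly iid sampling).
    """
    m, p = draws.spec.n_vars, draws.spec.lag_order
    n_lag = m * p
    coef_cols = range(n_lag) if not include_deterministic else range(draws.B_draws.shape[1])
    coef_ifs = []
    for col in coef_cols:
        for eq in range(m):
            chain = draws.B_draws[:, col, eq]
            if np.ptp(chain) > 0:
                coef_ifs.append(inefficiency_factor(chain))
    cov_ifs = []
    for i in range(m):
        for j in range(i, m):
            chain = draws.Omega_draws[:, i, j]
            if np.ptp(chain) > 0:
                cov_ifs.append(inefficiency_factor(chain))
    return {
        "n_retained": draws.n_retained,
        "coefficients": {
            "n_monitored": len(coef_ifs),
            "min": float(np.min(coef_ifs)),
            "max": float(np.max(coef_ifs)),
        },
        "covariance": {
            "n_monitored": len(cov_ifs),
            "min": float(np.min(cov_ifs)),
            "max": float(np.max(cov_ifs)),
        },
    }
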