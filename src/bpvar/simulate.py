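"""Synthetic panel VAR data with known ground truth.

Generates balanced country-year panels from a stationary VAR(P) with country
fixed effects, country-specific linear trends and correlated Gaussian
innovations — the statistical structure the estimator assumes — so the whole
pipeline can be exercised and validated offline, with the generating
parameters available for recovery checks.

`make_study_fixture` emulates the scale of the motivating application: 103
emerging-market and developing countries observed over 25 years (1995-2019)
on five jointly endogenous variables ordered uncertainty first, health
indicator last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import PanelDataset

STUDY_VARIABLES = ["uncertainty", "gdp", "co2", "health_exp", "health_indicator"]
INCOME_TIERS = ["low", "lower_middle", "upper_middle", "high"]
MARKET_CLASSES = ["emerging", "developing"]


def companion_matrix(lag_coefficients: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Companion form of a VAR(P): an (M·P) × (M·P) block matrix."""
    coefs = [np.asarray(a, float) for a in lag_coefficients]
    m = coefs[0].shape[0]
    p = len(coefs)
    comp = np.zeros((m * p, m * p))
    comp[:m] = np.hstack(coefs)
    if p > 1:
        comp[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    return comp


def spectral_radius(lag_coefficients: list[np.ndarray] | np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(companion_matrix(lag_coefficients))).max())


@dataclass
class SimulationTruth:
    """Generating parameters of a panel VAR with unit-specific deterministics.

    The dynamics (lag coefficients, innovation covariance) are common across
    countries; heterogeneity enters only through the fixed effects ``alpha``
    and trend slopes ``beta``, matching the homogeneous-slope panel model the
    estimator targets.
    """

    n_countries: int
    n_years: int
    n_vars: int
    lag_order: int
    lag_coefficients: list[np.ndarray]
    innovation_covariance: np.ndarray
    fixed_effects: np.ndarray          # (n_countries, n_vars)
    trend_slopes: np.ndarray           # (n_countries, n_vars)
    seed: int
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lag_coefficients = [np.asarray(a, float) for a in self.lag_coefficients]
        self.innovation_covariance = np.asarray(self.innovation_covariance, float)
        self.fixed_effects = np.asarray(self.fixed_effects, float)
        self.trend_slopes = np.asarray(self.trend_slopes, float)
        if not self.variable_names:
            self.variable_names = [f"y{i}" for i in range(self.n_vars)]
        if len(self.lag_coefficients) != self.lag_order:
            raise ValueError("need one coefficient matrix per lag")
        for a in self.lag_coefficients:
            if a.shape != (self.n_vars, self.n_vars):
                raise ValueError("lag coefficient matrices must be n_vars × n_vars")
        omega = self.innovation_covariance
        if omega.shape != (self.n_vars, self.n_vars) or not np.allclose(omega, omega.T):
            raise ValueError("innovation covariance must be square symmetric")
        if np.linalg.eigvalsh(omega).min() <= 0:
            raise ValueError("innovation covariance must be positive definite")
        if self.fixed_effects.shape != (self.n_countries, self.n_vars):
            raise ValueError("fixed_effects must be (n_countries, n_vars)")
        if self.trend_slopes.shape != (self.n_countries, self.n_vars):
            raise ValueError("trend_slopes must be (n_countries, n_vars)")
        if spectral_radius(self.lag_coefficients) >= 1.0:
            raise ValueError("lag coefficients are non-stationary (spectral radius ≥ 1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_countries": self.n_countries,
            "n_years": self.n_years,
            "n_vars": self.n_vars,
            "lag_order": self.lag_order,
            "lag_coefficients": [a.tolist() for a in self.lag_coefficients],
            "innovation_covariance": self.innovation_covariance.tolist(),
            "fixed_effects": self.fixed_effects.tolist(),
            "trend_slopes": self.trend_slopes.tolist(),
            "seed": self.seed,
            "variable_names": self.variable_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


def random_stable_var(
    n_vars: int,
    lag_order: int,
    max_spectral_radius: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Draw lag coefficient matrices whose companion matrix is stable.

    Gaussian matrices are rescaled (all lags jointly) until the companion
    spectral radius is at most ``max_spectral_radius``; scaling lag ``j`` by
    ``s**j`` rescales every companion eigenvalue by ``s``, so one step lands
    exactly on target when the raw draw is explosive.
    """
    if not 0 < max_spectral_radius < 1:
        raise ValueError("max_spectral_radius must lie in (0, 1)")
    if n_vars < 1 or lag_order < 1:
        raise ValueError("n_vars and lag_order must be ≥ 1")
    rng = np.random.default_rng(seed)
    coefs = [rng.normal(scale=0.4 / np.sqrt(n_vars), size=(n_vars, n_vars)) for _ in range(lag_order)]
    rho = spectral_radius(coefs)
    if rho > max_spectral_radius:
        s = max_spectral_radius / rho
        coefs = [a * s ** (j + 1) for j, a in enumerate(coefs)]
    return coefs


def random_spd(n: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """Random SPD matrix: scale²·(I + W W′/n) with W standard normal."""
    w = rng.normal(size=(n, n))
    return scale**2 * (np.eye(n) + w @ w.T / n)


def simulate_panel(truth: SimulationTruth, burn_in_periods: int = 100) -> PanelDataset:
    """Simulate a balanced panel from ``truth``.

    Each country's vector series follows
    ``y_t = alpha_i + beta_i·t + Σ_j A_j y_{t-j} + u_t`` with
    ``u_t ~ N(0, Ω)``, t indexing years 0..T-1 within country.  Countries are
    initialized at their deterministic steady state and ``burn_in_periods``
    pre-sample steps are discarded so the retained sample carries no
    initial-condition transient.
    """
    if burn_in_periods < 0:
        raise ValueError("burn_in_periods must be ≥ 0")
    rng = np.random.default_rng(truth.seed)
    n, t_len, m, p = truth.n_countries, truth.n_years, truth.n_vars, truth.lag_order
    asum = sum(truth.lag_coefficients)
    chol = np.linalg.cholesky(truth.innovation_covariance)
    # steady state of the no-trend system, used as the starting point
    steady = np.linalg.solve(np.eye(m) - asum, truth.fixed_effects.T).T  # (n, m)

    total = burn_in_periods + t_len
    shocks = rng.standard_normal((n, total, m)) @ chol.T
    records = np.empty((n, t_len, m))
    for i in range(n):
        hist = [steady[i].copy() for _ in range(p)]
        for t in range(total):
            t_trend = max(t - burn_in_periods, 0)  # trend clock starts at the sample
            y = truth.fixed_effects[i] + truth.trend_slopes[i] * t_trend + shocks[i, t]
            for j, a in enumerate(truth.lag_coefficients):
                y = y + a @ hist[j]
            hist = [y] + hist[:-1]
            if t >= burn_in_periods:
                records[i, t - burn_in_periods] = y

    frame = pd.DataFrame(
        records.reshape(n * t_len, m), columns=truth.variable_names
    )
    frame.insert(0, "year", np.tile(np.arange(t_len), n))
    frame.insert(0, "country", np.repeat([f"C{i:03d}" for i in range(n)], t_len))
    return PanelDataset(frame, list(truth.variable_names))


def _study_group_labels(countries: list[str]) -> dict[str, dict[str, str]]:
    """Deterministic stratified split: first 40% emerging, tiers round-robin."""
    n = len(countries)
    n_emerging = int(round(0.4 * n))
    labels = {}
    for i, c in enumerate(countries):
        labels[c] = {
            "market_class": MARKET_CLASSES[0] if i < n_emerging else MARKET_CLASSES[1],
            "income_tier": INCOME_TIERS[i % len(INCOME_TIERS)],
        }
    return labels


def make_study_fixture(
    seed: int = 0,
    n_countries: int = 103,
    n_years: int = 25,
    first_year: int = 1995,
) -> tuple[PanelDataset, SimulationTruth]:
    """Study-scale fixture: 103 countries × 25 years × 5 variables, VAR(1).

    Variables carry the recursive ordering of the application (uncertainty
    first, health indicator last).  All variables other than the uncertainty
    index are interpreted as log levels, so no further log transform is
    needed before estimation.  Country heterogeneity: fixed effects with
    s.d. 1, trend slopes with s.d. 0.01 — modest deterministic drift against
    unit-scale innovations.  Each country carries an emerging/developing flag
    and one of four income tiers for subsample runs.
    """
    rng = np.random.default_rng(seed)
    m = len(STUDY_VARIABLES)
    coefs = random_stable_var(m, 1, max_spectral_radius=0.85, seed=rng)
    # persistent own-lag dynamics, typical of annual macro levels
    coefs[0] = 0.6 * np.eye(m) + 0.4 * coefs[0]
    rho = spectral_radius(coefs)
    if rho > 0.95:
        coefs = [a * 0.95 / rho for a in coefs]
    omega = random_spd(m, rng, scale=0.05)
    truth = SimulationTruth(
        n_countries=n_countries,
        n_years=n_years,
        n_vars=m,
        lag_order=1,
        lag_coefficients=coefs,
        innovation_covariance=omega,
        fixed_effects=rng.normal(scale=1.0, size=(n_countries, m)),
        trend_slopes=rng.normal(scale=0.01, size=(n_countries, m)),
        seed=int(rng.integers(2**31 - 1)),
        variable_names=list(STUDY_VARIABLES),
    )
    panel = simulate_panel(truth)
    panel.frame["year"] = panel.frame["year"] + first_year
    panel.group_labels = _study_group_labels(panel.countries)
    return panel, truth
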