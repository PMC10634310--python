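"""Fixed-effects panel VAR estimated by a two-block Gibbs sampler.

The model, for country i and year t,

    y_it = alpha_i + beta_i * t + A_1 y_{i,t-1} + ... + A_P y_{i,t-P} + u_it,
    u_it ~ N(0, Omega),

pools the lag dynamics ``A_j`` and the innovation covariance ``Omega`` across
countries while absorbing country heterogeneity in per-country intercepts and
linear trends.  Shrinkage is imposed through dummy observations: artificial
rows appended to the data so that conjugate least squares on the augmented
sample implements a Minnesota-type prior (own lags centred on ``gamma``,
tightness ``tau``, linear lag decay), a loose prior on the deterministic
terms (scale ``c``), and a sum-of-coefficients prior (scale ``lam``).

The two conditional posteriors are standard conjugate forms:

    B | Omega ~ N(B*, Omega ⊗ (X*'X*)^{-1}),   B* = (X*'X*)^{-1} X*'Y*
    Omega | B ~ IW(S*, n* - K),                S* = (Y* - X*B)'(Y* - X*B)

with starred quantities computed on the dummy-augmented (stacked) sample of
n* = n_obs + TD rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .data import PanelDataset


@dataclass(frozen=True)
class VARSpec:
    """Model order, recursive variable ordering, and deterministic terms."""

    variable_order: tuple[str, ...]
    lag_order: int = 1
    include_fixed_effects: bool = True
    include_country_trends: bool = True

    def __post_init__(self) -> None:
        if self.lag_order < 1:
            raise ValueError("lag_order must be ≥ 1")
        if not self.variable_order or len(set(self.variable_order)) != len(self.variable_order):
            raise ValueError("variable_order must be non-empty and unique")

    @property
    def n_vars(self) -> int:
        return len(self.variable_order)


@dataclass
class RegressorMatrices:
    """Stacked response and regressor blocks of the panel VAR.

    Column layout of ``X``: first the M·P lag columns (lag-major: lag 1 of
    every variable, then lag 2, ...), then one dummy column per country, then
    one per-country trend column carrying the within-country time index on
    that country's rows and zero elsewhere.
    """

    Y: np.ndarray
    X: np.ndarray
    column_map: dict[str, int]
    n_countries: int
    ex: int  # number of exogenous (deterministic) columns

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]

    @property
    def n_lag_columns(self) -> int:
        return self.K - self.ex


@dataclass
class PriorHyperparams:
    """Dummy-observation prior settings.

    gamma : prior mean of each variable's first own lag (1 = random walk,
        appropriate for persistent log levels).
    tau : tightness of the lag-coefficient prior; smaller = tighter.
    c : scale of the prior on deterministic terms; small = loose.
    lam : sum-of-coefficients scale; larger = looser.
    sigma : per-variable residual scales from initial AR(1) regressions.
    mu : per-variable pre-sample means.
    """

    gamma: float
    tau: float
    c: float
    lam: float
    sigma: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, float)
        self.mu = np.asarray(self.mu, float)
        if self.tau <= 0 or self.c <= 0 or self.lam <= 0:
            raise ValueError("tau, c and lam must be strictly positive")
        if (self.sigma <= 0).any():
            raise ValueError("all sigma scales must be strictly positive")


@dataclass
class DummyObservations:
    """Artificial data rows implementing the prior; layout matches X."""

    YD: np.ndarray
    XD: np.ndarray
    block_labels: list[str]

    @property
    def TD(self) -> int:
        return self.YD.shape[0]

    @classmethod
    def empty(cls, n_vars: int, k: int) -> "DummyObservations":
        return cls(np.zeros((0, n_vars)), np.zeros((0, k)), [])


@dataclass(frozen=True)
class GibbsConfig:
    """MCMC schedule. The reference schedule is 55,000 total / 45,000 burn-in."""

    n_total: int = 55_000
    n_burn: int = 45_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_burn < self.n_total:
            raise ValueError("need 0 ≤ n_burn < n_total")
        if self.thin < 1 or (self.n_total - self.n_burn) // self.thin < 1:
            raise ValueError("retained draw count must be ≥ 1")

    @property
    def n_retained(self) -> int:
        return (self.n_total - self.n_burn) // self.thin


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws plus the analytic posterior location."""

    B_draws: np.ndarray        # (retained, K, M)
    Omega_draws: np.ndarray    # (retained, M, M)
    B_star: np.ndarray         # (K, M)
    column_map: dict[str, int]
    spec: VARSpec
    config: GibbsConfig

    @property
    def n_retained(self) -> int:
        return self.B_draws.shape[0]

    def save(self, stem: str | Path) -> None:
        """Write draws as <stem>.npz plus <stem>.json metadata."""
        stem = Path(stem)
        np.savez_compressed(
            stem.with_suffix(".npz"),
            B_draws=self.B_draws, Omega_draws=self.Omega_draws, B_star=self.B_star,
        )
        meta = {
            "column_map": self.column_map,
            "spec": {
                "variable_order": list(self.spec.variable_order),
                "lag_order": self.spec.lag_order,
                "include_fixed_effects": self.spec.include_fixed_effects,
                "include_country_trends": self.spec.include_country_trends,
            },
            "config": {
                "n_total": self.config.n_total, "n_burn": self.config.n_burn,
                "thin": self.config.thin, "seed": self.config.seed,
            },
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, stem: str | Path) -> "PosteriorDraws":
        stem = Path(stem)
        arrays = np.load(stem.with_suffix(".npz"))
        meta = json.loads(stem.with_suffix(".json").read_text())
        spec = VARSpec(
            tuple(meta["spec"]["variable_order"]), meta["spec"]["lag_order"],
            meta["spec"]["include_fixed_effects"], meta["spec"]["include_country_trends"],
        )
        return cls(
            arrays["B_draws"], arrays["Omega_draws"], arrays["B_star"],
            meta["column_map"], spec, GibbsConfig(**meta["config"]),
        )


# -- design construction ---------------------------------------------------


def build_design(panel: PanelDataset, spec: VARSpec) -> RegressorMatrices:
    """Stack country-year rows into (Y, X) for the panel VAR.

    Lags never cross country boundaries: the first P years of each country
    serve only as lag values.  The within-country trend index runs 0..T-1
    over the country's panel years, of which rows t = P..T-1 enter Y.
    """
    if not panel.is_balanced():
        raise ValueError("build_design requires a balanced panel")
    data = panel.to_arrays()  # (N, T, M)
    n, t_len, m = data.shape
    p = spec.lag_order
    if t_len <= p:
        raise ValueError(f"need T > P; got T={t_len}, P={p}")
    if tuple(panel.variable_order) != tuple(spec.variable_order):
        raise ValueError("panel variable order does not match spec ordering")

    rows_per_country = t_len - p
    n_obs = n * rows_per_country
    ex = n * int(spec.include_fixed_effects) + n * int(spec.include_country_trends)
    k = m * p + ex
    y = np.empty((n_obs, m))
    x = np.zeros((n_obs, k))
    column_map: dict[str, int] = {}
    for j in range(p):
        for v_idx, v in enumerate(spec.variable_order):
            column_map[f"lag{j + 1}:{v}"] = j * m + v_idx
    col = m * p
    countries = panel.countries
    fe_cols, tr_cols = {}, {}
    if spec.include_fixed_effects:
        for c in countries:
            column_map[f"fe:{c}"] = col
            fe_cols[c] = col
            col += 1
    if spec.include_country_trends:
        for c in countries:
            column_map[f"trend:{c}"] = col
            tr_cols[c] = col
            col += 1

    for i, c in enumerate(countries):
        sl = slice(i * rows_per_country, (i + 1) * rows_per_country)
        y[sl] = data[i, p:]
        for j in range(p):
            x[sl, j * m:(j + 1) * m] = data[i, p - 1 - j:t_len - 1 - j]
        if spec.include_fixed_effects:
            x[sl, fe_cols[c]] = 1.0
        if spec.include_country_trends:
            x[sl, tr_cols[c]] = np.arange(p, t_len)
    return RegressorMatrices(y, x, column_map, n, ex)


def estimate_scales(panel: PanelDataset, spec: VARSpec) -> np.ndarray:
    """Residual scale of a pooled AR(1) fit with country intercepts, per variable.

    These are the sigma_i entering the dummy-observation prior; pooling the
    AR(1) regression across countries (with country intercepts) matches the
    homogeneous-dynamics assumption of the panel VAR itself.
    """
    data = panel.to_arrays()
    n, t_len, m = data.shape
    sigma = np.empty(m)
    for v in range(m):
        y = data[:, 1:, v]
        ylag = data[:, :-1, v]
        # country intercepts absorbed by within-country demeaning
        yc = (y - y.mean(axis=1, keepdims=True)).ravel()
        xc = (ylag - ylag.mean(axis=1, keepdims=True)).ravel()
        denom = xc @ xc
        if denom <= 1e-12 * max(1.0, float(yc @ yc)):
            raise ValueError(f"variable {panel.variable_order[v]!r} has (near) zero lag variance")
        rho = (xc @ yc) / denom
        resid = yc - rho * xc
        dof = yc.size - n - 1
        s2 = resid @ resid / dof
        if s2 <= 0 or not np.isfinite(s2):
            raise ValueError(f"degenerate AR(1) residual scale for {panel.variable_order[v]!r}")
        sigma[v] = np.sqrt(s2)
    if (sigma <= 0).any():
        raise ValueError("zero residual scale; variable constant or perfectly persistent")
    return sigma


def presample_means(panel: PanelDataset, spec: VARSpec) -> np.ndarray:
    """Mean of each variable's first P observations per country, averaged over countries."""
    data = panel.to_arrays()
    return data[:, : spec.lag_order, :].mean(axis=(0, 1))


def default_hyperparams(
    panel: PanelDataset,
    spec: VARSpec,
    gamma: float = 1.0,
    tau: float = 1.0,
    c: float = 0.001,
    lam: float = 10.0,
) -> PriorHyperparams:
    """Hyperparameters at the loose reference settings, with data-based scales."""
    return PriorHyperparams(
        gamma=gamma, tau=tau, c=c, lam=lam,
        sigma=estimate_scales(panel, spec),
        mu=presample_means(panel, spec),
    )


def build_dummies(spec: VARSpec, hyper: PriorHyperparams, n_countries: int) -> DummyObservations:
    """Construct the dummy-observation blocks encoding the prior.

    Four stacked blocks, TD = M·P + M + 1 + M rows in total:

    - coefficient prior (M·P rows): the row for (variable m, lag j) puts
      j·sigma_m/tau on the corresponding lag column of XD, and gamma·sigma_m/tau
      on YD column m when j = 1 (zero otherwise) — own first lags shrink
      toward gamma, everything else toward zero, tighter at longer lags;
    - covariance prior (M rows): YD = diag(sigma), XD = 0;
    - deterministic-terms prior (1 row): XD = c on every exogenous column;
    - sum-of-coefficients prior (M rows): YD = diag(gamma·mu)/lam and the same
      diagonal replicated across every lag block of XD, shrinking each
      variable's summed lag coefficients toward gamma.
    """
    m, p = spec.n_vars, spec.lag_order
    if hyper.sigma.shape != (m,) or hyper.mu.shape != (m,):
        raise ValueError("sigma and mu must have one entry per endogenous variable")
    ex = n_countries * int(spec.include_fixed_effects) + n_countries * int(spec.include_country_trends)
    k = m * p + ex
    td = m * p + m + 1 + m
    yd = np.zeros((td, m))
    xd = np.zeros((td, k))
    labels: list[str] = []

    r = 0
    for j in range(1, p + 1):
        for v in range(m):
            if j == 1:
                yd[r, v] = hyper.gamma * hyper.sigma[v] / hyper.tau
            xd[r, (j - 1) * m + v] = j * hyper.sigma[v] / hyper.tau
            labels.append("coef_prior")
            r += 1
    for v in range(m):
        yd[r, v] = hyper.sigma[v]
        labels.append("cov_prior")
        r += 1
    xd[r, m * p:] = hyper.c
    labels.append("exog_prior")
    r += 1
    soc = hyper.gamma * hyper.mu / hyper.lam
    for v in range(m):
        yd[r, v] = soc[v]
        for j in range(p):
            xd[r, j * m + v] = soc[v]
        labels.append("sum_of_coefs")
        r += 1
    return DummyObservations(yd, xd, labels)


def stack_with_dummies(
    design: RegressorMatrices, dummies: DummyObservations
) -> tuple[np.ndarray, np.ndarray]:
    """Row-concatenate actual data with dummy observations: (Y*, X*)."""
    if dummies.TD == 0:
        return design.Y, design.X
    if dummies.XD.shape[1] != design.K or dummies.YD.shape[1] != design.Y.shape[1]:
        raise ValueError("dummy observation columns do not match the design layout")
    return np.vstack([design.Y, dummies.YD]), np.vstack([design.X, dummies.XD])


# -- conditional posteriors ------------------------------------------------


def _chol_gram(x_star: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of X*'X*, with a rank-deficiency diagnosis."""
    gram = x_star.T @ x_star
    try:
        return np.linalg.cholesky(gram)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(x_star)
        raise np.linalg.LinAlgError(
            f"X*'X* is rank deficient (rank {rank} < {x_star.shape[1]}); "
            "add dummy observations or drop collinear columns"
        ) from None


def posterior_location(y_star: np.ndarray, x_star: np.ndarray) -> np.ndarray:
    """B* = (X*'X*)^{-1} X*'Y*, solved by Cholesky factorization."""
    low = _chol_gram(x_star)
    return sla.cho_solve((low, True), x_star.T @ y_star)


def draw_coefficients(
    omega: np.ndarray,
    y_star: np.ndarray,
    x_star: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of B | Omega ~ N(B*, Omega ⊗ (X*'X*)^{-1}).

    Uses the matrix-normal factorization B = B* + A Z C' with A A' = (X*'X*)^{-1}
    and C C' = Omega, so the full K·M × K·M covariance is never formed.
    """
    low = _chol_gram(x_star)
    b_star = sla.cho_solve((low, True), x_star.T @ y_star)
    return _draw_coefficients_factored(b_star, low, omega, rng)


def _draw_coefficients_factored(
    b_star: np.ndarray, gram_chol: np.ndarray, omega: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    try:
        omega_chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("Omega draw is not positive definite") from None
    z = rng.standard_normal(b_star.shape)
    return b_star + sla.solve_triangular(gram_chol.T, z, lower=False) @ omega_chol.T


def draw_covariance(
    b: np.ndarray,
    y_star: np.ndarray,
    x_star: np.ndarray,
    td: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of Omega | B ~ IW(S*, n + TD - K) on the stacked sample."""
    n_actual = y_star.shape[0] - td
    k, m = b.shape
    dof = n_actual + td - k
    if dof <= m - 1:
        raise ValueError(f"inverse-Wishart dof {dof} must exceed M-1 = {m - 1}")
    resid = y_star - x_star @ b
    s_star = resid.T @ resid
    return _draw_covariance_scale(s_star, dof, rng)


def _draw_covariance_scale(s_star: np.ndarray, dof: int, rng: np.random.Generator) -> np.ndarray:
    s_star = 0.5 * (s_star + s_star.T)
    if np.linalg.eigvalsh(s_star).min() <= -1e-10 * max(np.trace(s_star), 1e-300) or np.trace(s_star) <= 0:
        raise ValueError("residual scale matrix S* is singular; residuals degenerate")
    return stats.invwishart.rvs(df=dof, scale=s_star, random_state=rng)


def run_gibbs(
    design: RegressorMatrices,
    dummies: DummyObservations,
    config: GibbsConfig,
    spec: VARSpec | None = None,
) -> PosteriorDraws:
    """Two-block Gibbs sampler alternating Omega | B and B | Omega.

    Initialized at the stacked least-squares solution (B*, S*/dof); the
    quantities that do not change along the chain — the Gram factor, B* and
    X*'Y* — are computed once.
    """
    y_star, x_star = stack_with_dummies(design, dummies)
    k, m = x_star.shape[1], y_star.shape[1]
    dof = y_star.shape[0] - k
    if dof <= m - 1:
        raise ValueError(f"dof {dof} too small for an M={m} system")
    low = _chol_gram(x_star)
    b_star = sla.cho_solve((low, True), x_star.T @ y_star)

    rng = np.random.default_rng(config.seed)
    b = b_star
    n_keep = config.n_retained
    b_draws = np.empty((n_keep, k, m))
    omega_draws = np.empty((n_keep, m, m))
    kept = 0
    for it in range(config.n_total):
        try:
            resid = y_star - x_star @ b
            omega = _draw_covariance_scale(resid.T @ resid, dof, rng)
            b = _draw_coefficients_factored(b_star, low, omega, rng)
        except (ValueError, np.linalg.LinAlgError) as err:
            raise RuntimeError(f"Gibbs iteration {it} failed: {err}") from err
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0 and kept < n_keep:
            b_draws[kept] = b
            omega_draws[kept] = omega
            kept += 1
    if spec is None:
        spec = VARSpec(tuple(f"y{i}" for i in range(m)), max((design.K - design.ex) // m, 1))
    return PosteriorDraws(b_draws, omega_draws, b_star, dict(design.column_map), spec, config)


def lag_block(b: np.ndarray, n_vars: int, lag_order: int) -> list[np.ndarray]:
    """Extract [A_1, ..., A_P] from a stacked coefficient matrix B (K × M).

    Row block (j-1)·M..j·M of B holds lag j's coefficients with variables on
    columns (equation index), so each A_j is the transposed row block.
    """
    return [b[j * n_vars:(j + 1) * n_vars, :].T for j in range(lag_order)]
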