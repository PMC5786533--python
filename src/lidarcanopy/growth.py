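"""Growth-curve fitting, growth rates, and trait/yield statistics.

The growth model is the three-parameter logistic (3PLM)

    y(t) = x0 * xn / (x0 + (xn - x0) * exp(-tau * (t - T)))

where t is days after planting (DAP), x0 the trait value on the reference
day T (the first observation day), xn the upper asymptote, and tau the rate
coefficient per day.  Parameters are estimated by non-linear least squares
with positivity bounds; confidence intervals come from the Jacobian at the
optimum.  ``LogisticGrowth`` / ``LogisticGrowthResults`` follow the
model-object convention of statsmodels: build the model from data, call
``fit()``, read estimates and diagnostics off the results object.

Also here: interval growth rates (difference quotients), one-way cultivar
ANOVA per trait and date, simple trait-vs-yield regression (R² per cultivar
or pooled), and a seeded generator of synthetic per-plot season tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LogisticGrowth",
    "LogisticGrowthResults",
    "YieldRecord",
    "logistic3",
    "growth_rate",
    "cultivar_anova",
    "trait_yield_regression",
    "simulate_field_season",
    "PAPER_DAP_GRID",
]

log = logging.getLogger(__name__)

#: canonical sampling calendar (DAP) whose consecutive pairs are the P1..P8 intervals
PAPER_DAP_GRID = (43, 45, 52, 67, 74, 88, 95, 102, 109)


def logistic3(t, x0: float, xn: float, tau: float, T: float = 45.0):
    """Evaluate the three-parameter logistic curve; y(T) = x0 exactly."""
    t = np.asarray(t, dtype=np.float64)
    return x0 * xn / (x0 + (xn - x0) * np.exp(-tau * (t - T)))


@dataclass(frozen=True)
class YieldRecord:
    plot_id: str
    cultivar: str
    yield_g: float

    def __post_init__(self):
        if self.yield_g < 0:
            raise ValueError("yield must be non-negative")


class LogisticGrowth:
    """3PLM growth model for one trait series.

    Parameters
    ----------
    t : array of observation days (DAP)
    y : positive trait values at those days
    T : reference day; defaults to the first observation day.
    """

    def __init__(self, t, y, T: float | None = None):
        self.t = np.asarray(t, dtype=np.float64).reshape(-1)
        self.y = np.asarray(y, dtype=np.float64).reshape(-1)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if self.t.size < 4:
            raise ValueError("need at least 4 observations to fit 3 parameters")
        if np.any(self.y <= 0):
            raise ValueError("trait values must be positive")
        if np.unique(self.t).size != self.t.size:
            raise ValueError("duplicate observation days")
        self.T = float(self.t.min() if T is None else T)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y_col: str, t_col: str = "dap", T: float | None = None):
        return cls(df[t_col].to_numpy(), df[y_col].to_numpy(), T=T)

    # ------------------------------------------------------------------
    def predict(self, params, t):
        x0, xn, tau = params
        return logistic3(t, x0, xn, tau, self.T)

    def fit(
        self,
        start_params=None,
        truncate_at_max: bool = False,
        maxiter: int = 2000,
    ) -> "LogisticGrowthResults":
        """Bounded non-linear least squares.

        Initialization: x0 <- first observation, xn <- max observation,
        tau <- 0.1/day.  ``truncate_at_max`` drops observations after the
        series maximum (defoliation-phase handling); by default the full
        series is fitted through any late decline.
        """
        t, y = self.t, self.y
        order = np.argsort(t)
        t, y = t[order], y[order]
        if truncate_at_max:
            imax = int(np.argmax(y))
            t, y = t[: imax + 1], y[: imax + 1]
            if t.size < 4:
                raise ValueError("too few observations left after truncation at the maximum")
        if start_params is None:
            start_params = np.array([y[0], float(np.max(y)), 0.1])
        p0 = np.clip(np.asarray(start_params, dtype=np.float64), 1e-9, None)

        def resid(p):
            return logistic3(t, p[0], p[1], p[2], self.T) - y

        sol = optimize.least_squares(
            resid,
            p0,
            bounds=(np.full(3, 1e-12), np.full(3, np.inf)),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=maxiter,
        )
        params = sol.x
        res = resid(params)
        sse = float(res @ res)
        n, k = t.size, 3
        dof = max(n - k, 1)
        s2 = sse / dof
        J = sol.jac
        JTJ = J.T @ J
        flags: list[str] = []
        if not sol.success:
            flags.append(f"non-convergence: {sol.message}")
        try:
            cov = s2 * np.linalg.inv(JTJ)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
            bse = np.full(3, np.nan)
            flags.append("singular Jacobian: parameters not identifiable")
        # flat series: x0 ~ xn makes tau drop out of the model
        if abs(params[1] - params[0]) < 1e-6 * max(params[1], 1e-12) or (
            np.isfinite(bse[2]) and params[2] > 0 and bse[2] > 1e3 * params[2]
        ):
            flags.append("tau unidentifiable (series has no resolvable growth)")
        if flags:
            log.warning("3PLM fit flags: %s", "; ".join(flags))
        return LogisticGrowthResults(
            model=self,
            params=params,
            bse=bse,
            cov_params=cov,
            sse=sse,
            nobs=n,
            df_resid=dof,
            converged=sol.success,
            flags=flags,
        )


@dataclass
class LogisticGrowthResults:
    """Fitted 3PLM: estimates, linearized uncertainties, diagnostics."""

    model: LogisticGrowth
    params: np.ndarray  # (x0, xn, tau)
    bse: np.ndarray
    cov_params: np.ndarray
    sse: float
    nobs: int
    df_resid: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    param_names = ("x0", "xn", "tau")

    @property
    def x0(self) -> float:
        return float(self.params[0])

    @property
    def xn(self) -> float:
        return float(self.params[1])

    @property
    def tau(self) -> float:
        return float(self.params[2])

    def predict(self, t):
        """Closed-form curve evaluation at day(s) t."""
        return self.model.predict(self.params, t)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Linearized (Jacobian) 1-alpha intervals, rows (lower, upper)."""
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def bootstrap_conf_int(self, alpha: float = 0.05, n_boot: int = 500, seed: int = 0) -> np.ndarray:
        """Residual-bootstrap intervals (slower, non-Gaussian-robust option)."""
        rng = np.random.default_rng(seed)
        t, y = self.model.t, self.model.y
        fitted = self.predict(t)
        resid = y - fitted
        draws = []
        for _ in range(n_boot):
            yb = np.clip(fitted + rng.choice(resid, size=resid.size, replace=True), 1e-9, None)
            try:
                r = LogisticGrowth(t, yb, T=self.model.T).fit(start_params=self.params)
                draws.append(r.params)
            except Exception:
                continue
        draws = np.array(draws)
        lo = np.quantile(draws, alpha / 2, axis=0)
        hi = np.quantile(draws, 1 - alpha / 2, axis=0)
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Three-parameter logistic growth fit",
            f"  nobs = {self.nobs}, T = {self.model.T:g} DAP, SSE = {self.sse:.6g}, converged = {self.converged}",
            f"  {'param':>5s} {'estimate':>12s} {'std err':>12s} {'[0.025':>12s} {'0.975]':>12s}",
        ]
        for i, name in enumerate(self.param_names):
            lines.append(
                f"  {name:>5s} {self.params[i]:>12.6g} {self.bse[i]:>12.4g} {ci[i, 0]:>12.6g} {ci[i, 1]:>12.6g}"
            )
        for f in self.flags:
            lines.append(f"  flag: {f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observations and fitted curve (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.t
        ax.plot(t, self.model.y, "o", label="observed")
        tt = np.linspace(t.min(), t.max(), 200)
        ax.plot(tt, self.predict(tt), "-", label="3PLM fit")
        ax.set_xlabel("days after planting")
        ax.set_ylabel("trait value")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Growth rate and field statistics
# ---------------------------------------------------------------------------


def _interval_labels(t: np.ndarray) -> list[str]:
    grid = np.asarray(PAPER_DAP_GRID, dtype=float)
    if 2 <= t.size <= grid.size:
        for s in range(grid.size - t.size + 1):
            if np.allclose(t, grid[s : s + t.size]):
                return [f"P{s + i + 1}" for i in range(t.size - 1)]
    return [f"I{i + 1}" for i in range(t.size - 1)]


def growth_rate(t, P) -> pd.DataFrame:
    """Per-interval growth rate GR = (P_t - P_{t-dt}) / dt.

    Returns a DataFrame (t_start, t_end, interval, gr); intervals matching
    the canonical sampling calendar are labelled P1..P8.
    """
    t = np.asarray(t, dtype=np.float64).reshape(-1)
    P = np.asarray(P, dtype=np.float64).reshape(-1)
    if t.shape != P.shape:
        raise ValueError("t and P must have equal length")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate dates in series")
    order = np.argsort(t)
    t, P = t[order], P[order]
    if t.size < 2:
        return pd.DataFrame(columns=["t_start", "t_end", "interval", "gr"])
    gr = np.diff(P) / np.diff(t)
    return pd.DataFrame(
        {"t_start": t[:-1], "t_end": t[1:], "interval": _interval_labels(t), "gr": gr}
    )


def cultivar_anova(
    traits: pd.DataFrame,
    value_cols,
    group_col: str = "cultivar",
    date_col: str = "dap",
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of cultivar on each trait, per date.

    Returns a long DataFrame (dap, trait, F, p).  Requires >= 2 groups with
    >= 2 plots each on every date.  P-values are reported uncorrected across
    dates and traits; apply ``statsmodels`` BH correction externally if
    multiplicity control is wanted.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    rows = []
    for dap, sub in traits.groupby(date_col):
        groups = [g for _, g in sub.groupby(group_col)]
        if len(groups) < 2:
            raise ValueError(f"date {dap}: need >= 2 cultivar groups")
        for trait in value_cols:
            samples = [g[trait].dropna().to_numpy() for g in groups]
            if any(s.size < 2 for s in samples):
                raise ValueError(f"date {dap}, trait {trait}: every group needs >= 2 plots")
            F, p = stats.f_oneway(*samples)
            rows.append({"dap": dap, "trait": trait, "F": float(F), "p": float(p)})
    return pd.DataFrame(rows)


def trait_yield_regression(
    traits: pd.DataFrame,
    yields: pd.DataFrame,
    value_cols,
    by: str = "cultivar",
    date_col: str = "dap",
) -> pd.DataFrame:
    """Simple OLS of yield on each trait, per date (and cultivar unless pooled).

    Returns a long DataFrame (dap, trait, cultivar, n, slope, r2).  R² is
    NaN (flagged in the log) when the trait has zero variance; fewer than 3
    matched plots is an error.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    if by not in ("cultivar", "pooled"):
        raise ValueError("by must be 'cultivar' or 'pooled'")
    merged = traits.merge(yields, on="plot_id", how="inner", suffixes=("", "_y"))
    rows = []
    for dap, sub in merged.groupby(date_col):
        groups = [("all", sub)] if by == "pooled" else list(sub.groupby("cultivar"))
        for cult, g in groups:
            for trait in value_cols:
                gg = g[[trait, "yield_g"]].dropna()
                if len(gg) < 3:
                    raise ValueError(f"date {dap}, cultivar {cult}: fewer than 3 matched plots")
                x = gg[trait].to_numpy()
                yv = gg["yield_g"].to_numpy()
                if np.ptp(x) < 1e-15:
                    log.warning("date %s, cultivar %s, trait %s: zero variance, R2 undefined", dap, cult, trait)
                    rows.append({"dap": dap, "trait": trait, "cultivar": cult, "n": len(gg),
                                 "slope": np.nan, "r2": np.nan})
                    continue
                res = stats.linregress(x, yv)
                rows.append({"dap": dap, "trait": trait, "cultivar": cult, "n": len(gg),
                             "slope": float(res.slope), "r2": float(res.rvalue**2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic season tables
# ---------------------------------------------------------------------------

# per-cultivar season parameters: upper asymptotes of the three traits and
# mean final yield, reflecting a four-cultivar cotton trial of 32 plots each
_CULTIVAR_DEFAULTS = {
    "cultivar1": {"ch": 1.08, "pca": 2.73, "pv": 2.75, "yield": 928.51},
    "cultivar2": {"ch": 1.08, "pca": 2.23, "pv": 2.17, "yield": 781.58},
    "cultivar3": {"ch": 0.96, "pca": 2.47, "pv": 2.11, "yield": 954.18},
    "cultivar4": {"ch": 0.88, "pca": 2.34, "pv": 1.59, "yield": 937.22},
}


def simulate_field_season(
    seed: int = 0,
    dates=(45, 52, 67, 74, 88, 95, 102, 109),
    plots_per_cultivar: int = 32,
    cultivars: dict | None = None,
    T: float = 45.0,
    tau: float = 0.12,
    noise_frac: float = 0.04,
    yield_sd: float = 80.0,
    yield_trait_coupling: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded synthetic per-plot trait and yield tables for a season.

    Each plot's trait trajectories follow 3PLM curves whose asymptotes vary
    around cultivar means (8% CV plot effect) with multiplicative
    observation noise; final yield combines the cultivar mean, a coupling to
    the plot's volume asymptote, and Gaussian noise.  Returns
    (traits_df, yields_df) in the interchange layout of the growth stage.
    """
    rng = np.random.default_rng(seed)
    cultivars = cultivars or _CULTIVAR_DEFAULTS
    dates = np.asarray(dates, dtype=float)
    t_rows, y_rows = [], []
    for cult, pars in cultivars.items():
        for p in range(plots_per_cultivar):
            plot_id = f"{cult}_p{p:02d}"
            effect = rng.normal(1.0, 0.08)
            asym = {k: pars[k] * effect for k in ("ch", "pca", "pv")}
            tau_p = tau * rng.normal(1.0, 0.1)
            for d in dates:
                row = {"plot_id": plot_id, "cultivar": cult, "dap": d}
                for k in ("ch", "pca", "pv"):
                    x0 = 0.12 * asym[k]
                    val = logistic3(d, x0, asym[k], tau_p, T)
                    row["max_ch" if k == "ch" else k] = val * rng.normal(1.0, noise_frac)
                t_rows.append(row)
            yld = (
                pars["yield"]
                + yield_trait_coupling * pars["yield"] * (effect - 1.0)
                + rng.normal(0.0, yield_sd)
            )
            y_rows.append({"plot_id": plot_id, "cultivar": cult, "yield_g": max(float(yld), 0.0)})
    return pd.DataFrame(t_rows), pd.DataFrame(y_rows)
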