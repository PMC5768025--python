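"""Initial-rate extraction, ping-pong bi-bi fitting, and design identifiability.

The estimation chain mirrors the experimental workflow: a flow-ramp series
gives product-vs-residence-time points; the low-conversion window yields an
initial rate; rates collected over a grid of glucose and dissolved-O2
levels are fit to the two-substrate rate law by multi-start nonlinear
least squares; linearized or bootstrap confidence intervals quantify the
estimates; and Fisher-information analysis compares candidate designs
(e.g. atmospheric-only vs combined atmospheric + 6 bar oxygen windows)
without generating any data.

Identifiability is the scientific crux: at a single dissolved-O2 level
only the apparent constants V_max,app and K_MS,app are identifiable — the
oxygen Michaelis constant K_MO is absorbed into both.  Spanning oxygen
levels well below and well above K_MO (the 5-to-10-fold bracketing rule)
is what makes all three parameters estimable, and what the pressurized
reactor makes physically possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import KineticParams, specific_rate

__all__ = [
    "RateObservation",
    "FitOptions",
    "FitResult",
    "DesignSpec",
    "RATE_TABLE_COLUMNS",
    "extract_initial_rate",
    "fit_ping_pong",
    "confidence_intervals",
    "estimate_activity_scaling",
    "compare_designs",
    "observations_to_frame",
    "frame_to_observations",
]

RATE_TABLE_COLUMNS = ["glucose_mM", "o2_mM", "rate_umol_min_mg", "weight", "campaign"]

#: Covariance condition number above which a fit is flagged ill-identified.
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class RateObservation:
    """One specific initial-rate measurement at (glucose, dissolved O2)."""

    S: float
    O: float
    rate: float
    weight: float = 1.0
    campaign: str = "A"

    def __post_init__(self) -> None:
        if self.S < 0 or self.O < 0:
            raise ValueError("concentrations must be >= 0")
        if not self.weight > 0:
            raise ValueError("weight must be > 0")


def observations_to_frame(obs: list[RateObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.S, o.O, o.rate, o.weight, o.campaign) for o in obs], columns=RATE_TABLE_COLUMNS
    )


def frame_to_observations(df: pd.DataFrame) -> list[RateObservation]:
    missing = [c for c in RATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate table missing column(s): {', '.join(missing)}")
    return [
        RateObservation(
            S=float(r.glucose_mM),
            O=float(r.o2_mM),
            rate=float(r.rate_umol_min_mg),
            weight=float(r.weight),
            campaign=str(r.campaign),
        )
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class FitOptions:
    """Nonlinear least-squares options.

    n_starts log-uniform multi-starts are drawn over ``start_span`` decades
    around an automatic scale guess (max rate, median O, median S);
    parameters are fit in log space, which enforces positivity without
    constraints.  ``weighting='relative'`` divides residuals by the
    observed rate, matching a multiplicative error model; the default is
    absolute (unweighted beyond per-point ``weight``) least squares.
    """

    n_starts: int = 20
    start_span: tuple[float, float] = (0.01, 100.0)
    weighting: str = "absolute"  # or "relative"
    seed: int = 0
    xtol: float = 1e-12
    ftol: float = 1e-12

    def __post_init__(self) -> None:
        if self.weighting not in ("absolute", "relative"):
            raise ValueError("weighting must be 'absolute' or 'relative'")
        if self.n_starts < 1:
            raise ValueError("need at least one start")


@dataclass
class FitResult:
    """Point estimates with covariance, 95 % CIs and identifiability flags."""

    params: KineticParams
    covariance: np.ndarray
    ci95: dict[str, tuple[float, float]]
    rss: float
    n_obs: int
    converged: bool
    condition_flag: bool
    extra: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "params": {
                "kcat_umol_min_mg": self.params.kcat,
                "Kmo_mM": self.params.K_MO,
                "Kms_mM": self.params.K_MS,
            },
            "covariance": np.asarray(self.covariance).tolist(),
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "condition_flag": self.condition_flag,
            **{k: v for k, v in self.extra.items() if _json_safe(v)},
        }
        return json.dumps(payload, indent=indent)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass(frozen=True)
class DesignSpec:
    """An experimental design: support points, replicate counts, noise model.

    points are (S, O) pairs [mM]; replicates may be a scalar applied to all
    points.  ``noise_cv`` is the relative standard deviation of a rate
    measurement.  Full three-parameter identifiability calls for at least
    3 distinct levels in each substrate.
    """

    points: tuple[tuple[float, float], ...]
    replicates: tuple[int, ...] | int = 1
    noise_cv: float = 0.03

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("design needs at least one support point")
        if not self.noise_cv > 0:
            raise ValueError("noise_cv must be > 0")
        reps = self.replicate_counts()
        if len(reps) != len(self.points) or any(r < 1 for r in reps):
            raise ValueError("replicates must be positive and match points")

    def replicate_counts(self) -> tuple[int, ...]:
        if isinstance(self.replicates, int):
            return (self.replicates,) * len(self.points)
        return tuple(self.replicates)

    def scaled(self, factor: int) -> "DesignSpec":
        return replace(self, replicates=tuple(r * factor for r in self.replicate_counts()))


# ---------------------------------------------------------------------------
# initial rates


def extract_initial_rate(
    series: pd.DataFrame,
    enzyme_mg_mL: float,
    S0_mM: float,
    max_conversion: float = 0.10,
    campaign: str = "A",
) -> RateObservation:
    """Specific initial rate from a concentration-residence-time series.

    Keeps the rows with conversion <= ``max_conversion`` (the initial-rate
    window, default 10 %), fits product concentration vs residence time by
    a least-squares line through the origin (product is zero at tau = 0 by
    construction), and divides the slope by the enzyme concentration to
    obtain the specific rate.  The observation's dissolved O2 is the mean
    over the retained rows.
    """
    if enzyme_mg_mL <= 0:
        raise ValueError("enzyme concentration must be > 0")
    mask = series["conversion"].to_numpy() <= max_conversion
    if int(mask.sum()) < 3:
        raise ValueError(
            "conversion exceeds initial-rate window: fewer than 3 rows at "
            f"conversion <= {max_conversion}"
        )
    tau = series.loc[mask, "residence_time_min"].to_numpy(dtype=float)
    P = series.loc[mask, "product_mM"].to_numpy(dtype=float)
    slope = float(np.sum(P * tau) / np.sum(tau * tau))  # through-origin LS
    return RateObservation(
        S=S0_mM,
        O=float(series.loc[mask, "o2_mM"].mean()),
        rate=slope / enzyme_mg_mL,
        campaign=campaign,
    )


# ---------------------------------------------------------------------------
# nonlinear fitting


def _rate_and_grad(theta: np.ndarray, S: np.ndarray, O: np.ndarray):
    """Model rate and its gradient wrt (kcat, K_MO, K_MS)."""
    kcat, kmo, kms = theta
    den = S * O + kmo * S + kms * O
    r = kcat * S * O / den
    g = np.empty((S.size, 3))
    g[:, 0] = r / kcat
    g[:, 1] = -r * S / den
    g[:, 2] = -r * O / den
    return r, g


def _exp_clip(x):
    # wild multi-starts can wander; clip log-params to a huge but finite box
    return np.exp(np.clip(x, -60.0, 60.0))


def _residual_factory(S, O, rate, sqw):
    def resid(x):
        r, _ = _rate_and_grad(_exp_clip(x), S, O)
        return sqw * (rate - r)

    def jac(x):
        theta = _exp_clip(x)
        _, g = _rate_and_grad(theta, S, O)
        return -sqw[:, None] * g * theta[None, :]  # chain rule to log space

    return resid, jac


def _effective_sqrt_weights(obs: list[RateObservation], weighting: str) -> np.ndarray:
    w = np.array([o.weight for o in obs], dtype=float)
    if weighting == "relative":
        r = np.array([max(abs(o.rate), 1e-12) for o in obs])
        w = w / r**2
    return np.sqrt(w)


def _start_points(
    scale: np.ndarray, options: FitOptions, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = np.log(options.start_span)
    starts = [np.log(scale)]  # scale guess itself is the first start
    for _ in range(options.n_starts - 1):
        starts.append(np.log(scale) + rng.uniform(lo, hi, size=scale.size))
    return np.asarray(starts)


def _cov_and_cis(theta, J_theta, rss, n, k):
    """sigma^2 (J'J)^-1 covariance and t-based 95 % CIs; inf on singularity."""
    JtJ = J_theta.T @ J_theta
    dof = max(n - k, 1)
    sigma2 = rss / dof
    cond = np.linalg.cond(JtJ)
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.inf)
    tcrit = stats.t.ppf(0.975, dof)
    half = tcrit * np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    cis = {i: (theta[i] - half[i], theta[i] + half[i]) for i in range(k)}
    return cov, cis, half, cond


def fit_ping_pong(obs: list[RateObservation], options: FitOptions | None = None) -> FitResult:
    """Fit (kcat, K_MO, K_MS) to initial rates by multi-start least squares.

    Minimizes sum_i w_i (rate_i - r_E(S_i, O_i; theta))^2 over
    log-parameters (positivity by construction), from ``n_starts``
    log-uniform starting points around an automatic scale guess; the best
    converged start wins.  ``condition_flag`` is set when the normal-matrix
    condition number exceeds 1e8 or any relative 95 % CI half-width exceeds
    100 % — the signature of a design that cannot separate K_MO from the
    apparent constants (e.g. a single oxygen level).
    """
    options = options or FitOptions()
    if len(obs) < 3:
        raise ValueError("need at least 3 observations to fit 3 parameters")
    S = np.array([o.S for o in obs], dtype=float)
    O = np.array([o.O for o in obs], dtype=float)
    rate = np.array([o.rate for o in obs], dtype=float)
    if not np.any(rate > 0):
        raise ValueError("no positive rates in the data")
    sqw = _effective_sqrt_weights(obs, options.weighting)

    scale = np.array([max(rate.max(), 1e-6), max(np.median(O), 1e-6), max(np.median(S), 1e-6)])
    rng = np.random.default_rng(options.seed)
    resid, jac = _residual_factory(S, O, rate, sqw)

    best = None
    for x0 in _start_points(scale, options, rng):
        try:
            sol = optimize.least_squares(
                resid, x0, jac=jac, method="lm", xtol=options.xtol, ftol=options.ftol
            )
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("no multi-start converged; check the rate table")

    theta = np.exp(best.x)
    rss = float(2 * best.cost)
    _, g = _rate_and_grad(theta, S, O)
    J_theta = -sqw[:, None] * g
    cov, cis_idx, half, cond = _cov_and_cis(theta, J_theta, rss, len(obs), 3)
    names = ("kcat", "K_MO", "K_MS")
    ci95 = {names[i]: cis_idx[i] for i in range(3)}
    rel_half = half / theta
    flag = bool(cond > CONDITION_LIMIT or np.any(rel_half > 1.0) or not np.all(np.isfinite(half)))
    return FitResult(
        params=KineticParams.from_array(theta),
        covariance=cov,
        ci95=ci95,
        rss=rss,
        n_obs=len(obs),
        converged=True,
        condition_flag=flag,
        extra={"condition_number": float(cond), "weighting": options.weighting},
    )


def confidence_intervals(
    fit: FitResult,
    obs: list[RateObservation],
    method: str = "linearized",
    n_boot: int = 200,
    seed: int = 0,
    options: FitOptions | None = None,
) -> FitResult:
    """Refresh the 95 % CIs of a converged fit.

    ``linearized`` re-derives t-based intervals from the stored covariance;
    ``bootstrap`` resamples residuals with replacement, refits each
    pseudo-dataset from the point estimate, and takes percentile intervals
    (seeded, hence reproducible).  More than 20 % refit failures aborts.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    names = ("kcat", "K_MO", "K_MS")
    if method == "linearized":
        theta = fit.params.as_array()
        half = stats.t.ppf(0.975, max(fit.n_obs - 3, 1)) * np.sqrt(
            np.clip(np.diag(fit.covariance), 0.0, np.inf)
        )
        fit.ci95 = {names[i]: (theta[i] - half[i], theta[i] + half[i]) for i in range(3)}
        fit.extra["ci_method"] = "linearized"
        return fit
    if method != "bootstrap":
        raise ValueError("method must be 'linearized' or 'bootstrap'")

    options = options or FitOptions()
    S = np.array([o.S for o in obs], dtype=float)
    O = np.array([o.O for o in obs], dtype=float)
    fitted = specific_rate(S, O, fit.params)
    residuals = np.array([o.rate for o in obs]) - fitted
    sqw = _effective_sqrt_weights(obs, options.weighting)
    rng = np.random.default_rng(seed)
    x_hat = np.log(fit.params.as_array())

    draws, failures = [], 0
    for _ in range(n_boot):
        y_star = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        resid, jac = _residual_factory(S, O, y_star, sqw)
        try:
            sol = optimize.least_squares(resid, x_hat, jac=jac, method="lm")
            if not sol.success:
                raise RuntimeError
            draws.append(np.exp(sol.x))
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"bootstrap refit failure rate {failures}/{n_boot} exceeds 20 %")
    draws_arr = np.asarray(draws)
    lo = np.percentile(draws_arr, 2.5, axis=0)
    hi = np.percentile(draws_arr, 97.5, axis=0)
    fit.ci95 = {names[i]: (float(lo[i]), float(hi[i])) for i in range(3)}
    fit.extra["ci_method"] = "bootstrap"
    fit.extra["n_boot_ok"] = len(draws)
    return fit


def estimate_activity_scaling(
    obs_a: list[RateObservation],
    obs_b: list[RateObservation],
    options: FitOptions | None = None,
) -> dict:
    """Joint two-campaign fit with shared Michaelis constants.

    Enzyme formulations lose activity between campaigns; under the
    ping-pong law a uniform activity loss scales kcat only, leaving K_MO
    and K_MS untouched.  The model therefore has four parameters
    (kcat_A, kcat_B, shared K_MO, shared K_MS); the returned ``ratio`` is
    kcat_B/kcat_A, the between-campaign degradation factor.
    """
    options = options or FitOptions()
    if not obs_a or not obs_b:
        raise ValueError("both campaigns must be non-empty")
    Sa, Oa = (np.array([o.S for o in obs_a]), np.array([o.O for o in obs_a]))
    Sb, Ob = (np.array([o.S for o in obs_b]), np.array([o.O for o in obs_b]))
    ra = np.array([o.rate for o in obs_a])
    rb = np.array([o.rate for o in obs_b])
    sqw = np.concatenate(
        [_effective_sqrt_weights(obs_a, options.weighting),
         _effective_sqrt_weights(obs_b, options.weighting)]
    )
    y = np.concatenate([ra, rb])
    S = np.concatenate([Sa, Sb])
    O = np.concatenate([Oa, Ob])
    is_b = np.concatenate([np.zeros(ra.size, bool), np.ones(rb.size, bool)])

    def resid(x):
        kcat_a, kcat_b, kmo, kms = _exp_clip(x)
        den = S * O + kmo * S + kms * O
        kcat = np.where(is_b, kcat_b, kcat_a)
        return sqw * (y - kcat * S * O / den)

    scale = np.array(
        [max(ra.max(), 1e-6), max(rb.max(), 1e-6), max(np.median(O), 1e-6), max(np.median(S), 1e-6)]
    )
    rng = np.random.default_rng(options.seed)
    lo, hi = np.log(options.start_span)
    best = None
    for i in range(options.n_starts):
        x0 = np.log(scale) + (rng.uniform(lo, hi, 4) if i else 0.0)
        try:
            sol = optimize.least_squares(
                resid, x0, method="lm", xtol=options.xtol, ftol=options.ftol
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("joint campaign fit did not converge from any start")
    kcat_a, kcat_b, kmo, kms = np.exp(best.x)
    return {
        "K_MO": float(kmo),
        "K_MS": float(kms),
        "kcat_A": float(kcat_a),
        "kcat_B": float(kcat_b),
        "ratio": float(kcat_b / kcat_a),
        "rss": float(2 * best.cost),
    }


# ---------------------------------------------------------------------------
# design identifiability


def fisher_information(design: DesignSpec, truth: KineticParams) -> np.ndarray:
    """Fisher information of (kcat, K_MO, K_MS) at ``truth`` for a design.

    Relative Gaussian noise: Var[rate at (S,O)] = (noise_cv * r_E)^2, so
    each support point contributes n_reps * g g^T / sigma^2 with g the
    rate gradient.  Points with zero true rate carry no information.
    """
    F = np.zeros((3, 3))
    theta = truth.as_array()
    for (S, O), reps in zip(design.points, design.replicate_counts()):
        if S <= 0 or O <= 0:
            continue
        r, g = _rate_and_grad(theta, np.array([S]), np.array([O]))
        sigma = design.noise_cv * r[0]
        if sigma <= 0:
            continue
        F += reps * np.outer(g[0], g[0]) / sigma**2
    return F


def compare_designs(
    designs: list[DesignSpec], truth: KineticParams
) -> pd.DataFrame:
    """Linearized relative standard errors of each parameter per design.

    Inverts the Fisher information at the true parameters; no data are
    generated.  A singular (or numerically singular) information matrix —
    e.g. every oxygen level far above K_MO — yields infinite SEs rather
    than an exception: the design simply cannot estimate that parameter.
    Values are SE divided by the true parameter (dimensionless).
    """
    rows = []
    theta = truth.as_array()
    for i, d in enumerate(designs):
        F = fisher_information(d, truth)
        if np.linalg.cond(F) > 1e15:
            rel = np.full(3, np.inf)
        else:
            rel = np.sqrt(np.diag(np.linalg.inv(F))) / theta
        rows.append((i, *rel))
    return pd.DataFrame(
        rows, columns=["design", "rel_se_kcat", "rel_se_K_MO", "rel_se_K_MS"]
    ).set_index("design")
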