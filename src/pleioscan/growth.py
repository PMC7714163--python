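"""Nonlinear mixed-effects head-circumference growth model.

The trajectory model is a five-parameter Gompertz form with a nonlinear
deceleration term:

    Y_ij = (L + L_i) * exp(-(a + a_i) * exp(-b * t * (1 - th*(1 - exp(-(lam + lam_i)*t))))) + eps_ij

with population fixed effects (L, a, b, th, lam), independent subject
effects on (L, a, lam) with diagonal covariance, and i.i.d. residual
noise.  Fitting alternates penalized per-subject estimation of the random
effects with a Laplace/Lindstrom-Bates style linearized marginal
likelihood for the fixed effects and variance components.

Per-subject growth phenotypes are linf = L + L_i, alpha = a + a_i,
lambda = lam + lam_i.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

__all__ = [
    "GrowthPopulationParams",
    "GrowthObservations",
    "GrowthFitResult",
    "DEFAULT_POPULATION",
    "predict",
    "fit_population",
    "subject_effects",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when the mixed-model fit fails to converge; carries a trace."""

    def __init__(self, message: str, trace: list[dict] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class GrowthPopulationParams:
    """Population parameters: 5 fixed effects + 3 subject-effect variances + residual."""

    linf: float
    alpha: float
    beta: float
    theta: float
    lam: float
    var_linf: float = 0.0
    var_alpha: float = 0.0
    var_lam: float = 0.0
    var_resid: float = 0.0

    def __post_init__(self) -> None:
        if self.linf <= 0:
            raise ValueError("growth limit must be positive")
        for name in ("var_linf", "var_alpha", "var_lam", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def fixed(self) -> np.ndarray:
        return np.array([self.linf, self.alpha, self.beta, self.theta, self.lam])

    @property
    def variances(self) -> np.ndarray:
        return np.array([self.var_linf, self.var_alpha, self.var_lam])

    def to_dict(self) -> dict:
        return asdict(self)


#: Reference parameter set used as the simulator default (head circumference,
#: cm, against post-menstrual age in weeks).
DEFAULT_POPULATION = GrowthPopulationParams(
    linf=49.96582,
    alpha=5.62027,
    beta=0.10450,
    theta=0.75950,
    lam=0.01667,
    var_linf=1.305845,
    var_alpha=0.1648373,
    var_lam=0.0005637008,
    var_resid=0.7218403,
)


@dataclass
class GrowthObservations:
    """Longitudinal measurements: subject_id, time_weeks, hc_cm."""

    data: pd.DataFrame
    time_window: tuple[float, float] = (8.0, 290.0)

    def __post_init__(self) -> None:
        required = {"subject_id", "time_weeks", "hc_cm"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"growth observations require columns {sorted(required)}")
        t = self.data["time_weeks"].to_numpy(float)
        lo, hi = self.time_window
        if np.any((t < lo) | (t > hi)):
            raise ValueError(f"observation times outside window [{lo}, {hi}] weeks")

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].astype(str).drop_duplicates().tolist()

    def per_subject(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for sid, grp in self.data.groupby("subject_id", sort=False):
            out.append(
                (
                    str(sid),
                    grp["time_weeks"].to_numpy(float),
                    grp["hc_cm"].to_numpy(float),
                )
            )
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "GrowthObservations":
        return cls(data=pd.read_csv(path, sep="\t"), **kwargs)


def _model(t, L, a, b, th, lam):
    elt = np.exp(np.clip(-lam * t, -50.0, 50.0))
    g = b * t * (1.0 - th * (1.0 - elt))
    E = np.exp(-np.clip(g, -50.0, 50.0))
    return L * np.exp(np.clip(-a * E, -50.0, 50.0))


def predict(
    t: float | np.ndarray,
    params: GrowthPopulationParams,
    subject_effects: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Noise-free trajectory value(s) at time(s) ``t`` (weeks)."""
    t = np.asarray(t, dtype=float)
    dL, da, dlam = subject_effects
    return _model(t, params.linf + dL, params.alpha + da, params.beta, params.theta, params.lam + dlam)


def _jacobians(t, L, a, b, th, lam):
    """Value plus derivatives w.r.t. (L, a, b, th, lam)."""
    elt = np.exp(np.clip(-lam * t, -50.0, 50.0))
    u = 1.0 - th * (1.0 - elt)
    g = b * t * u
    E = np.exp(-np.clip(g, -50.0, 50.0))
    eaE = np.exp(np.clip(-a * E, -50.0, 50.0))
    f = L * eaE
    df_dL = eaE
    df_da = -E * f
    df_dg = a * f * E
    df_db = df_dg * (t * u)
    df_dth = df_dg * (-b * t * (1.0 - elt))
    df_dlam = df_dg * (-b * th * t * t * elt)
    return f, np.stack([df_dL, df_da, df_db, df_dth, df_dlam], axis=-1)


_BOUNDS_LO = np.array([1.0, 1e-2, 1e-4, 0.0, 1e-5])
_BOUNDS_HI = np.array([200.0, 30.0, 2.0, 0.999, 1.0])


def _grid_init(t, y):
    """Coarse grid over the shape parameters; growth limit from the data."""
    L0 = float(np.max(y)) * 1.02
    best, best_sse = None, np.inf
    for a in (2.0, 4.0, 6.0, 9.0):
        for b in (0.03, 0.1, 0.3):
            for th in (0.3, 0.6, 0.8):
                for lam in (0.005, 0.02, 0.08):
                    sse = float(np.sum((_model(t, L0, a, b, th, lam) - y) ** 2))
                    if sse < best_sse:
                        best, best_sse = (L0, a, b, th, lam), sse
    return np.array(best)


def _pooled_fit(t, y, x0=None):
    """Population-curve NLS ignoring subject effects; used for initialization."""
    if x0 is None:
        x0 = _grid_init(t, y)
    x0 = np.clip(x0, _BOUNDS_LO, _BOUNDS_HI)

    def resid(p):
        f, _ = _jacobians(t, *p)
        return f - y

    def jac(p):
        _, J = _jacobians(t, *p)
        return J

    sol = least_squares(resid, x0, jac=jac, bounds=(_BOUNDS_LO, _BOUNDS_HI))
    return sol.x


def _subject_blocks(obs: GrowthObservations):
    blocks = obs.per_subject()
    return blocks


def _conditional_modes(blocks, beta, d_var, s2):
    """Penalized NLS estimate of (L_i, a_i, lam_i) per subject."""
    L, a, b, th, lam = beta
    pen = np.sqrt(s2 / np.maximum(d_var, 1e-12))  # residual-scaled ridge weights
    modes = np.zeros((len(blocks), 3))
    for i, (_, t, y) in enumerate(blocks):
        if len(t) < 2:
            continue

        def resid(u, t=t, y=y):
            f = _model(t, L + u[0], a + u[1], b, th, lam + u[2])
            return np.concatenate([f - y, pen * u])

        def jac(u, t=t):
            _, J = _jacobians(t, L + u[0], a + u[1], b, th, lam + u[2])
            Jr = J[:, [0, 1, 4]]
            return np.vstack([Jr, np.diag(pen)])

        sol = least_squares(resid, modes[i], jac=jac, method="lm", max_nfev=60)
        modes[i] = sol.x
    return modes


def _linearize(blocks, beta, modes):
    """Pseudo-data (w_i, X_i, Z_i) for the linearized mixed model."""
    L, a, b, th, lam = beta
    out = []
    for (sid, t, y), u in zip(blocks, modes):
        f, J = _jacobians(t, L + u[0], a + u[1], b, th, lam + u[2])
        Z = J[:, [0, 1, 4]]
        # first-order expansion: y ~ f + X(beta*-beta) + Z(u*-u) + e
        w = y - f + (J @ beta) + (Z @ u)
        out.append((w, J, Z))
    return out


def _group_by_size(pseudo):
    """Batch subjects by observation count for vectorized likelihood."""
    groups: dict[int, list[int]] = {}
    for i, (w, X, Z) in enumerate(pseudo):
        groups.setdefault(len(w), []).append(i)
    batched = []
    for k, idx in groups.items():
        W = np.stack([pseudo[i][0] for i in idx])  # (S, k)
        X = np.stack([pseudo[i][1] for i in idx])  # (S, k, 5)
        Z = np.stack([pseudo[i][2] for i in idx])  # (S, k, 3)
        batched.append((W, X, Z))
    return batched


def _gls_and_neg2ll(log_theta, batched, return_beta=False, col_scale=None):
    """Profiled ML -2 log-likelihood of the linearized model.

    log_theta = log of (var_L, var_a, var_lam, var_resid).  ``col_scale``
    rescales the fixed-effect design columns (the parameters span four
    orders of magnitude) so the profiling solve stays well conditioned.
    """
    # variance floor keeps V positive definite on noiseless data
    v = np.exp(np.clip(log_theta, -16.0, 12.0))
    d, s2 = v[:3], max(v[3], 1e-7)
    scale = np.ones(5) if col_scale is None else np.asarray(col_scale, float)
    A = np.zeros((5, 5))
    rhs = np.zeros(5)
    pieces = []
    n_total = 0
    logdet_total = 0.0
    for W, X, Z in batched:
        S, k, _ = Z.shape
        V = np.einsum("ska,a,sla->skl", Z, d, Z) + s2 * np.eye(k)[None, :, :]
        # relative jitter guards the factorization when d dwarfs s2
        jitter = 1e-10 * np.einsum("skk->sk", V).max()
        V += jitter * np.eye(k)[None, :, :]
        Lc = np.linalg.cholesky(V)
        logdet_total += 2.0 * np.sum(np.log(np.einsum("skk->sk", Lc)))
        Xs = X * scale[None, None, :]
        Xw = np.linalg.solve(V, Xs)  # V^-1 Xs  (S,k,5)
        Ww = np.linalg.solve(V, W[..., None])[..., 0]  # V^-1 w
        A += np.einsum("ski,skj->ij", Xs, Xw)
        rhs += np.einsum("ski,sk->i", Xs, Ww)
        pieces.append((W, X, V))
        n_total += S * k
    beta = np.linalg.lstsq(A, rhs, rcond=None)[0] * scale
    quad = 0.0
    for W, X, V in pieces:
        r = W - np.einsum("skj,j->sk", X, beta)
        rV = np.linalg.solve(V, r[..., None])[..., 0]
        quad += np.einsum("sk,sk->", r, rV)
    neg2ll = logdet_total + quad + n_total * np.log(2 * np.pi)
    if return_beta:
        return neg2ll, beta, A
    return neg2ll


@dataclass
class GrowthFitResult:
    params: GrowthPopulationParams
    fixed_se: dict[str, float]
    n_subjects: int
    n_obs: int
    converged: bool
    n_iter: int
    neg2ll: float
    trace: list[dict]

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "fixed_se": self.fixed_se,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "neg2ll": self.neg2ll,
        }


def fit_population(
    obs: GrowthObservations,
    init: GrowthPopulationParams | None = None,
    max_outer: int = 8,
    tol: float = 1e-4,
) -> GrowthFitResult:
    """Fit fixed effects and variance components by alternating estimation.

    Starts from a pooled (no-random-effect) nonlinear least-squares fit,
    then alternates conditional-mode estimation of subject effects with a
    linearized marginal-likelihood update of the fixed effects and the
    four variance parameters.
    """
    blocks = _subject_blocks(obs)
    if any(len(t) < 2 for _, t, _ in blocks):
        n_bad = sum(len(t) < 2 for _, t, _ in blocks)
        raise ValueError(f"{n_bad} subject(s) have fewer than 2 observations")
    t_all = np.concatenate([t for _, t, _ in blocks])
    y_all = np.concatenate([y for _, _, y in blocks])

    x0 = init.fixed if init is not None else None
    beta = _pooled_fit(t_all, y_all, x0)

    # crude variance starting values from pooled residual spread
    f0, _ = _jacobians(t_all, *beta)
    resid_var = float(np.var(y_all - f0))
    if init is not None and init.var_resid > 0:
        theta = np.log(
            np.maximum(
                [init.var_linf, init.var_alpha, init.var_lam, init.var_resid], 1e-8
            )
        )
    else:
        theta = np.log(
            np.maximum([0.5 * resid_var, 0.05, 1e-4, 0.5 * resid_var], 1e-8)
        )

    trace: list[dict] = []
    converged = False
    neg2ll = np.inf
    A = np.eye(5)
    for it in range(max_outer):
        d = np.exp(theta[:3])
        s2 = np.exp(theta[3])
        modes = _conditional_modes(blocks, beta, d, s2)
        pseudo = _linearize(blocks, beta, modes)
        batched = _group_by_size(pseudo)
        col_scale = np.maximum(np.abs(beta), [1.0, 0.1, 0.01, 0.01, 1e-3])

        sol = minimize(
            _gls_and_neg2ll,
            theta,
            args=(batched, False, col_scale),
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-5, "fatol": 1e-5},
        )
        # restart from the incumbent: Nelder-Mead stalls on this surface
        sol2 = minimize(
            _gls_and_neg2ll,
            sol.x,
            args=(batched, False, col_scale),
            method="Nelder-Mead",
            options={"maxiter": 200, "xatol": 1e-6, "fatol": 1e-6},
        )
        theta_new = sol2.x if sol2.fun < sol.fun else sol.x
        neg2ll_new, beta_new, A = _gls_and_neg2ll(
            theta_new, batched, return_beta=True, col_scale=col_scale
        )
        beta_new = np.clip(beta_new, _BOUNDS_LO, _BOUNDS_HI)
        step = float(np.max(np.abs(beta_new - beta) / np.maximum(np.abs(beta), 1e-8)))
        trace.append(
            {
                "iter": it,
                "beta": beta_new.tolist(),
                "theta": theta_new.tolist(),
                "neg2ll": float(neg2ll_new),
                "rel_step": step,
            }
        )
        beta, theta = beta_new, theta_new
        if step < tol and abs(neg2ll - neg2ll_new) < 1e-3 * (1 + abs(neg2ll_new)):
            neg2ll = neg2ll_new
            converged = True
            break
        neg2ll = neg2ll_new
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(theta)):
        raise FitError("growth model fit diverged", trace)

    v = np.exp(theta)
    cov = np.linalg.inv(A)  # scaled coordinates: cov(beta) = S cov S
    se = col_scale * np.sqrt(np.maximum(np.diag(cov), 0.0))
    params = GrowthPopulationParams(
        linf=float(beta[0]),
        alpha=float(beta[1]),
        beta=float(beta[2]),
        theta=float(beta[3]),
        lam=float(beta[4]),
        var_linf=float(v[0]),
        var_alpha=float(v[1]),
        var_lam=float(v[2]),
        var_resid=float(v[3]),
    )
    return GrowthFitResult(
        params=params,
        fixed_se={
            "linf": float(se[0]),
            "alpha": float(se[1]),
            "beta": float(se[2]),
            "theta": float(se[3]),
            "lam": float(se[4]),
        },
        n_subjects=len(blocks),
        n_obs=len(t_all),
        converged=converged,
        n_iter=len(trace),
        neg2ll=float(neg2ll),
        trace=trace,
    )


def subject_effects(
    obs: GrowthObservations, pop: GrowthPopulationParams
) -> pd.DataFrame:
    """Conditional-mode subject effects, reported as absolute phenotypes.

    Returns one row per subject with columns subject_id, linf, alpha,
    lambda and a boolean ``flagged`` column marking subjects with fewer
    than 2 usable observations (whose effects are fixed at 0).
    """
    blocks = _subject_blocks(obs)
    d = np.maximum(pop.variances, 1e-12)
    s2 = max(pop.var_resid, 1e-12)
    modes = _conditional_modes(blocks, pop.fixed, d, s2)
    rows = []
    for (sid, t, _), u in zip(blocks, modes):
        flagged = len(t) < 2
        rows.append(
            {
                "subject_id": sid,
                "linf": pop.linf + (0.0 if flagged else u[0]),
                "alpha": pop.alpha + (0.0 if flagged else u[1]),
                "lambda": pop.lam + (0.0 if flagged else u[2]),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
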