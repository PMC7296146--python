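"""Per-day bivariate genotype-by-treatment mixed model.

For one trait on one day the carrier means are modelled as

    y_{gtc} = mu_t + (beta * x_g) + u_{gt} + eps_{gtc}

with fixed treatment means ``mu_t`` (and an optional per-genotype
covariate, e.g. a phenology score), random genotype-by-treatment effects
``(u_{gC}, u_{gD}) ~ N(0, G)`` with *unstructured* 2x2 covariance G, and
residuals ``eps ~ N(0, sigma2_e[t])`` heterogeneous by treatment (a
pooled-residual variant is available).  Estimation is by REML on the
5-parameter profile likelihood (fixed effects solved by generalized
least squares), with the G diagonal deliberately *not* constrained to be
non-negative: negative genotype-variance estimates are legitimate REML
solutions under this parameterization and are reported as such — the
genetic correlation is then undefined.

Derived quantities per fit: the Wald test of the mean drought effect
(chi-square, 1 df), the genetic correlation between conditions
``r_g = g_CD / sqrt(g_CC * g_DD)`` (defined only for positive diagonals,
truncated into [-1, 1] with a flag), the log2 fold change of genetic
variance ``log2(g_DD / g_CC)``, and the phenotypic correlation of
genotype means across conditions.

The optimizer is quasi-Newton (L-BFGS-B) started at closed-form ANOVA
moment estimates; standard errors come from the observed information
(numerical Hessian of the restricted log-likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

_PENALTY = 1e10
_VAR_FLOOR = 1e-12


class SingularDesignError(ValueError):
    """Too little data to fit the model for a given trait/day."""


@dataclass
class DayTraitFit:
    """REML result for one trait on one day."""

    trait: str
    day: int | None
    mu_control: float
    mu_drought: float
    var_g_control: float
    var_g_drought: float
    cov_g: float
    var_e_control: float
    var_e_drought: float
    wald: float
    pvalue: float
    converged: bool
    n_genotypes: int
    beta_covariate: float | None = None
    se: dict[str, float] = field(default_factory=dict)
    rg_truncated: bool = False

    @property
    def neglog10p(self) -> float:
        # chi2.logsf keeps resolution far beyond float underflow of the p-value
        return float(-stats.chi2.logsf(self.wald, 1) / np.log(10.0))

    @property
    def mean_drought_effect(self) -> float:
        return self.mu_drought - self.mu_control

    @property
    def genetic_correlation(self) -> float:
        return genetic_correlation(self)

    @property
    def log2fc(self) -> float:
        return genetic_variance_log2fc(self)


def _prepare(cm: pd.DataFrame, covariate: pd.Series | None):
    """Group one trait/day slice by genotype and by replication pattern.

    Rows are sorted (genotype, treatment) so every genotype's control
    observations precede its drought observations; genotypes sharing the
    same (n control, n drought) pattern are stacked into one value matrix
    so the likelihood handles them with a single V factorization.
    """
    genos = cm["genotype"].to_numpy()
    t = (cm["treatment"].to_numpy() == "drought").astype(np.int64)
    vals = cm["value"].to_numpy(dtype=float)
    codes, uniq = pd.factorize(genos, sort=True)
    n_g = len(uniq)
    order = np.lexsort((t, codes))
    vals_s = vals[order]
    nc = np.bincount(codes, weights=1 - t, minlength=n_g).astype(np.int64)
    nd = np.bincount(codes, weights=t, minlength=n_g).astype(np.int64)
    tot = nc + nd
    starts = np.r_[0, np.cumsum(tot)[:-1]]

    if covariate is not None:
        loose = []
        for g in range(n_g):
            if tot[g] == 0:
                continue
            x = float(covariate.get(uniq[g], np.nan))
            if not np.isfinite(x):
                continue
            y = vals_s[starts[g]:starts[g] + tot[g]]
            tvec = np.r_[np.zeros(nc[g], int), np.ones(nd[g], int)]
            loose.append((tvec, y, x))
        return None, loose

    packed = {}
    pat = nc * 1000 + nd  # composite pattern key; counts stay far below 1000
    for key in np.unique(pat[tot > 0]):
        sel = np.where((pat == key) & (tot > 0))[0]
        pc, pd_ = int(key // 1000), int(key % 1000)
        n = pc + pd_
        idx = starts[sel][:, None] + np.arange(n)[None, :]
        Y = vals_s[idx]
        Z = np.zeros((n, 2))
        Z[:pc, 0] = 1.0
        Z[pc:, 1] = 1.0
        packed[(pc, pd_)] = {"Y": Y, "X": Z.copy(), "Z": Z, "m": Y.shape[0]}
    return packed, None


def _pattern_neg2_reml(theta: np.ndarray, packed: dict) -> float:
    gcc, gdd, gcd, sc, sd = theta
    if sc <= 0 or sd <= 0:
        return _PENALTY
    G = np.array([[gcc, gcd], [gcd, gdd]])
    logdet_sum = 0.0
    quad_sum = 0.0
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for (nc, nd), blk in packed.items():
        Z, X, Y, m = blk["Z"], blk["X"], blk["Y"], blk["m"]
        R = np.r_[np.full(nc, sc), np.full(nd, sd)]
        V = Z @ G @ Z.T + np.diag(R)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return _PENALTY
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        logdet_sum += m * logdetV
        quad_sum += float(np.einsum("ij,jk,ik->", Y, Vinv, Y))
        A += m * (X.T @ Vinv @ X)
        b += X.T @ Vinv @ Y.sum(axis=0)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return _PENALTY
    beta = np.linalg.solve(A, b)
    quad = quad_sum - b @ beta
    return logdet_sum + logdetA + quad


def _loose_neg2_reml(theta: np.ndarray, loose: list) -> float:
    gcc, gdd, gcd, sc, sd = theta
    if sc <= 0 or sd <= 0:
        return _PENALTY
    G = np.array([[gcc, gcd], [gcd, gdd]])
    p = 3
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet_sum = 0.0
    quad_sum = 0.0
    for tvec, y, x in loose:
        n = y.size
        Z = np.zeros((n, 2))
        Z[tvec == 0, 0] = 1.0
        Z[tvec == 1, 1] = 1.0
        X = np.c_[Z, np.full(n, x)]
        V = Z @ G @ Z.T + np.diag(np.where(tvec == 0, sc, sd))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return _PENALTY
        logdet_sum += 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        A += X.T @ Vinv @ X
        b += X.T @ Vinv @ y
        quad_sum += float(y @ Vinv @ y)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return _PENALTY
    beta = np.linalg.solve(A, b)
    return logdet_sum + logdetA + quad_sum - b @ beta


def _pattern_neg2_reml_and_grad(
    theta: np.ndarray, packed: dict
) -> tuple[float, np.ndarray]:
    """Restricted -2 log-likelihood and its analytic gradient.

    Uses the standard REML derivative tr(P dV) - r' V^-1 dV V^-1 r with
    the fixed-effect projection folded in through A = sum X'V^-1 X; the
    five dV/dtheta are rank-one/diagonal, so every trace reduces to a few
    small products shared across genotypes of the same pattern.
    """
    gcc, gdd, gcd, sc, sd = theta
    if sc <= 0 or sd <= 0:
        return _PENALTY, np.zeros(5)
    G = np.array([[gcc, gcd], [gcd, gdd]])
    cache = []
    logdet_sum = 0.0
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for (nc, nd), blk in packed.items():
        Z, X, Y, m = blk["Z"], blk["X"], blk["Y"], blk["m"]
        R = np.r_[np.full(nc, sc), np.full(nd, sd)]
        V = Z @ G @ Z.T + np.diag(R)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return _PENALTY, np.zeros(5)
        logdet_sum += m * 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        C = Vinv @ X                       # n x 2
        A += m * (X.T @ C)
        b += C.T @ Y.sum(axis=0)
        cache.append(((nc, nd), Z, X, Y, m, Vinv, C))
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return _PENALTY, np.zeros(5)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    f = logdet_sum + logdetA
    grad = np.zeros(5)
    B = np.zeros((5, 2, 2))                # per-theta X'Vinv dV Vinv X
    for (nc, nd), Z, X, Y, m, Vinv, C in cache:
        Rm = Y - (X @ beta)[None, :]       # residuals, m x n
        U = Rm @ Vinv                      # m x n
        f += float((Rm * U).sum())
        z1, z2 = Z[:, 0], Z[:, 1]
        Cz1, Cz2 = C.T @ z1, C.T @ z2      # 2-vectors
        Uz1, Uz2 = U @ z1, U @ z2          # m-vectors
        diagV = np.diag(Vinv)
        # trace terms (sum over genotypes of the pattern)
        grad[0] += m * float(z1 @ Vinv @ z1)
        grad[1] += m * float(z2 @ Vinv @ z2)
        grad[2] += m * 2.0 * float(z1 @ Vinv @ z2)
        grad[3] += m * float(diagV[:nc].sum())
        grad[4] += m * float(diagV[nc:].sum())
        # quadratic-form terms
        grad[0] -= float((Uz1 * Uz1).sum())
        grad[1] -= float((Uz2 * Uz2).sum())
        grad[2] -= 2.0 * float((Uz1 * Uz2).sum())
        grad[3] -= float((U[:, :nc] ** 2).sum())
        grad[4] -= float((U[:, nc:] ** 2).sum())
        # fixed-effect projection terms
        B[0] += m * np.outer(Cz1, Cz1)
        B[1] += m * np.outer(Cz2, Cz2)
        B[2] += m * (np.outer(Cz1, Cz2) + np.outer(Cz2, Cz1))
        B[3] += m * (C[:nc].T @ C[:nc])
        B[4] += m * (C[nc:].T @ C[nc:])
    for i in range(5):
        grad[i] -= float((Ainv * B[i].T).sum())
    return f, grad


def _robust_inv(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M)


def _gls_fixed_effects(theta, packed, loose):
    """beta-hat and its covariance at the given variance parameters.

    Pseudo-inverses guard the degenerate noise-free limit where V is
    numerically singular; the GLS means remain exact there.
    """
    gcc, gdd, gcd, sc, sd = theta
    G = np.array([[gcc, gcd], [gcd, gdd]])
    if packed is not None:
        A = np.zeros((2, 2))
        b = np.zeros(2)
        for (nc, nd), blk in packed.items():
            Z, X, Y, m = blk["Z"], blk["X"], blk["Y"], blk["m"]
            V = Z @ G @ Z.T + np.diag(np.r_[np.full(nc, sc), np.full(nd, sd)])
            Vinv = _robust_inv(V)
            A += m * (X.T @ Vinv @ X)
            b += X.T @ Vinv @ Y.sum(axis=0)
    else:
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for tvec, y, x in loose:
            n = y.size
            Z = np.zeros((n, 2))
            Z[tvec == 0, 0] = 1.0
            Z[tvec == 1, 1] = 1.0
            X = np.c_[Z, np.full(n, x)]
            V = Z @ G @ Z.T + np.diag(np.where(tvec == 0, sc, sd))
            Vinv = _robust_inv(V)
            A += X.T @ Vinv @ X
            b += X.T @ Vinv @ y
    cov = _robust_inv(A)
    return cov @ b, cov


def moment_start(cm: pd.DataFrame) -> np.ndarray:
    """ANOVA moment estimates used to start the optimizer.

    Between-genotype covariance of treatment-wise genotype means minus
    residual/(carriers per cell); residual from within-cell mean squares.
    """
    tmask = (cm["treatment"].to_numpy() == "drought").astype(np.int64)
    vals = cm["value"].to_numpy(dtype=float)
    codes, _ = pd.factorize(cm["genotype"].to_numpy(), sort=True)
    n_g = codes.max() + 1
    resid = np.empty(2)
    nbar = np.empty(2)
    gmeans = np.full((n_g, 2), np.nan)
    for t in (0, 1):
        sel = tmask == t
        c, v = codes[sel], vals[sel]
        n = np.bincount(c, minlength=n_g)
        s = np.bincount(c, weights=v, minlength=n_g)
        s2 = np.bincount(c, weights=v * v, minlength=n_g)
        present = n > 0
        with np.errstate(invalid="ignore"):
            mean = s / n
        gmeans[present, t] = mean[present]
        ss = (s2 - n * np.square(np.where(present, mean, 0.0)))[present].sum()
        df_within = (n[present] - 1).sum()
        r = ss / df_within if df_within > 0 else 1.0
        resid[t] = r if r > 0 else _VAR_FLOOR * 1e6
        nbar[t] = n[present].mean() if present.any() else 1.0
    gcc = gdd = gcd = 0.0
    both = gmeans[np.isfinite(gmeans).all(axis=1)]
    if len(both) >= 2:
        S = np.cov(both[:, 0], both[:, 1], ddof=1)
        gcc = float(S[0, 0] - resid[0] / nbar[0])
        gdd = float(S[1, 1] - resid[1] / nbar[1])
        gcd = float(S[0, 1])
    # keep the start strictly inside the positive-definite region of V
    # (degenerate data put the moment estimate exactly on the boundary)
    gcc = max(gcc, -resid[0] / nbar[0] * (1.0 - 1e-6))
    gdd = max(gdd, -resid[1] / nbar[1] * (1.0 - 1e-6))
    cap = 0.999 * np.sqrt((gcc + resid[0] / nbar[0]) * (gdd + resid[1] / nbar[1]))
    gcd = float(np.clip(gcd, -cap, cap))
    return np.array([gcc, gdd, gcd, resid[0], resid[1]])


def fit_day_trait(
    cm: pd.DataFrame,
    trait: str | None = None,
    day: int | None = None,
    covariate: pd.Series | None = None,
    pooled_residual: bool = False,
    compute_se: bool = True,
    maxiter: int = 200,
) -> DayTraitFit:
    """REML fit of the bivariate G-by-treatment model to one trait/day slice.

    ``cm`` must contain the columns genotype, treatment, value (already
    restricted to one trait and day, or pass ``trait``/``day`` to slice).
    ``covariate`` is an optional per-genotype Series entering the fixed
    part (analysis-of-covariance variant).  ``pooled_residual`` ties the
    two residual variances together.
    """
    sub = cm
    if trait is not None and "trait" in sub.columns:
        sub = sub[sub["trait"] == trait]
    if day is not None and "day" in sub.columns:
        sub = sub[sub["day"] == day]
    if sub["value"].isna().any():
        sub = sub.dropna(subset=["value"])

    codes, _ = pd.factorize(sub["genotype"].to_numpy(), sort=False)
    is_d = (sub["treatment"].to_numpy() == "drought").astype(np.int64)
    n_top = codes.max() + 1 if len(codes) else 0
    has_c = np.bincount(codes, weights=1 - is_d, minlength=n_top) > 0
    has_d = np.bincount(codes, weights=is_d, minlength=n_top) > 0
    if int((has_c & has_d).sum()) < 2:
        raise SingularDesignError(
            f"trait {trait!r} day {day}: fewer than 2 genotypes observed "
            "in both treatments"
        )

    packed, loose = _prepare(sub, covariate)

    if packed is not None:
        def value_and_grad(th):
            return _pattern_neg2_reml_and_grad(th, packed)
    else:
        def value_and_grad(th):
            f = _loose_neg2_reml(th, loose)
            if f >= _PENALTY / 2:
                return f, np.zeros(th.size)
            g = optimize.approx_fprime(
                th, lambda t: _loose_neg2_reml(t, loose),
                1e-6 * np.maximum(np.abs(th), 1.0))
            return f, g

    if pooled_residual:
        base_vg = value_and_grad

        def value_and_grad(th):  # noqa: F811 - tied-residual reparameterization
            full = np.array([th[0], th[1], th[2], th[3], th[3]])
            f, g = base_vg(full)
            return f, np.r_[g[:3], g[3] + g[4]]

    def objective(th):
        return value_and_grad(th)[0]

    start_frame = sub
    if covariate is not None:
        # moment starts ignore the fixed covariate; remove a pooled OLS
        # estimate of its effect first so the start lands near the optimum
        xv = sub["genotype"].map(covariate).to_numpy(dtype=float)
        ok = np.isfinite(xv)
        yv = sub["value"].to_numpy(dtype=float)
        xc = xv[ok] - xv[ok].mean()
        denom = (xc ** 2).sum()
        if denom > 0:
            beta0 = float(xc @ (yv[ok] - yv[ok].mean()) / denom)
            start_frame = sub.loc[ok].assign(value=yv[ok] - beta0 * xv[ok])
        else:
            start_frame = sub.loc[ok]
    theta0 = moment_start(start_frame)
    if pooled_residual:
        theta0 = np.r_[theta0[:3], 0.5 * (theta0[3] + theta0[4])]
    bounds = [(None, None)] * 3 + [(_VAR_FLOOR, None)] * (1 if pooled_residual else 2)

    def _stationary(f_val, g) -> bool:
        return bool(np.max(np.abs(g)) < 1e-6 * max(1.0, abs(f_val)))

    f0, g0 = value_and_grad(theta0)
    if f0 < _PENALTY / 2 and _stationary(f0, g0):
        # the moment start already satisfies the REML stationarity
        # condition (exact on balanced data) — nothing to polish
        theta_opt, converged = theta0, True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                value_and_grad, theta0, method="L-BFGS-B", jac=True,
                bounds=bounds,
                # ftol is the operative rule (relative objective change)
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
            )
        theta_opt = res.x
        f_opt, g_opt = value_and_grad(res.x)
        converged = f_opt < _PENALTY / 2 and (
            bool(res.success) or _stationary(f_opt, g_opt)
        )
    theta = theta_opt
    if pooled_residual:
        theta = np.array([theta[0], theta[1], theta[2], theta[3], theta[3]])

    beta, cov_beta = _gls_fixed_effects(theta, packed, loose)
    contrast = np.zeros(beta.size)
    contrast[0], contrast[1] = -1.0, 1.0
    diff = float(contrast @ beta)
    var_diff = float(contrast @ cov_beta @ contrast)
    wald = diff * diff / var_diff if var_diff > 0 else 0.0
    pvalue = float(stats.chi2.sf(wald, 1))

    se: dict[str, float] = {}
    if compute_se and converged:
        try:
            H = approx_hess(theta_opt, objective)
            cov_theta = 2.0 * np.linalg.inv(H)
            sd = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
            names = (["var_g_control", "var_g_drought", "cov_g", "var_e"]
                     if pooled_residual else
                     ["var_g_control", "var_g_drought", "cov_g",
                      "var_e_control", "var_e_drought"])
            se = dict(zip(names, sd.tolist()))
        except np.linalg.LinAlgError:
            se = {}

    return DayTraitFit(
        trait=trait if trait is not None else "", day=day,
        mu_control=float(beta[0]), mu_drought=float(beta[1]),
        beta_covariate=float(beta[2]) if beta.size > 2 else None,
        var_g_control=float(theta[0]), var_g_drought=float(theta[1]),
        cov_g=float(theta[2]),
        var_e_control=float(theta[3]), var_e_drought=float(theta[4]),
        wald=float(wald), pvalue=pvalue, converged=converged,
        n_genotypes=int(sub["genotype"].nunique()), se=se,
    )


def wald_drought_test(fit: DayTraitFit) -> tuple[float, float, float]:
    """(W, p, -log10 p) for the mean drought effect; chi-square, 1 df."""
    if not fit.converged:
        raise ValueError("Wald test undefined on a non-converged fit")
    return fit.wald, fit.pvalue, fit.neglog10p


def genetic_correlation(fit: DayTraitFit) -> float:
    """g_CD / sqrt(g_CC * g_DD); NaN unless both diagonals are positive.

    Values outside [-1, 1] (possible because G is not forced positive
    semidefinite) are truncated and ``fit.rg_truncated`` is set.
    """
    if fit.var_g_control <= 0 or fit.var_g_drought <= 0:
        return float("nan")
    r = fit.cov_g / np.sqrt(fit.var_g_control * fit.var_g_drought)
    if abs(r) > 1.0:
        fit.rg_truncated = True
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


def genetic_variance_log2fc(fit: DayTraitFit) -> float:
    """log2 of drought-to-control genetic variance; NaN unless both > 0."""
    if fit.var_g_control <= 0 or fit.var_g_drought <= 0:
        return float("nan")
    return float(np.log2(fit.var_g_drought / fit.var_g_control))


def phenotypic_correlation(df: pd.DataFrame, trait: str | None = None) -> float:
    """Pearson correlation across genotypes of per-genotype mean value in
    control vs in drought.  NaN with < 3 genotypes or zero variance."""
    sub = df if trait is None else df[df["trait"] == trait]
    means = (
        sub.groupby(["genotype", "treatment"])["value"].mean().unstack("treatment")
    )
    if "control" not in means or "drought" not in means:
        return float("nan")
    both = means[["control", "drought"]].dropna()
    if len(both) < 3 or both["control"].std() == 0 or both["drought"].std() == 0:
        return float("nan")
    return float(np.corrcoef(both["control"], both["drought"])[0, 1])


@dataclass
class FitSurface:
    """All per-day fits for the accepted traits of one experiment."""

    fits: dict[tuple[str, int], DayTraitFit]

    def pvalue_table(self) -> pd.DataFrame:
        rows = [(t, d, f.pvalue, f.wald, f.converged)
                for (t, d), f in self.fits.items()]
        return pd.DataFrame(rows, columns=["trait", "day", "pvalue", "wald",
                                           "converged"])

    def log2fc_table(self) -> pd.DataFrame:
        rows = [(t, d, f.log2fc) for (t, d), f in self.fits.items()]
        return pd.DataFrame(rows, columns=["trait", "day", "log2fc"])

    def genetic_correlation_profiles(self) -> pd.DataFrame:
        """Wide day-by-trait frame of r_g (NaN where undefined)."""
        rows = [(t, d, f.genetic_correlation) for (t, d), f in self.fits.items()]
        long = pd.DataFrame(rows, columns=["trait", "day", "rg"])
        return long.pivot(index="trait", columns="day", values="rg")

    def median_log2fc_by_category(
        self, categories: dict[str, str]
    ) -> pd.DataFrame:
        """Per-day median log2 fold change of genetic variance, grouped by
        trait category (color/texture/geometric)."""
        tab = self.log2fc_table()
        tab["category"] = tab["trait"].map(categories)
        return (
            tab.dropna(subset=["log2fc", "category"])
            .groupby(["day", "category"])["log2fc"].median().unstack("category")
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (t, d), f in self.fits.items():
            for comp in ("mu_control", "mu_drought", "var_g_control",
                         "var_g_drought", "cov_g", "var_e_control",
                         "var_e_drought", "wald", "pvalue"):
                rows.append((t, d, comp, getattr(f, comp),
                             f.se.get(comp, np.nan)))
        return pd.DataFrame(rows, columns=["trait", "day", "component",
                                           "estimate", "se"])


def fit_surface(
    cm: pd.DataFrame,
    traits: list[str] | None = None,
    days: list[int] | None = None,
    covariate: pd.Series | None = None,
    compute_se: bool = False,
    pooled_residual: bool = False,
) -> FitSurface:
    """Fit the per-day model for every (accepted) trait and day."""
    traits = traits if traits is not None else sorted(cm["trait"].unique())
    days = days if days is not None else sorted(cm["day"].unique())
    fits = {}
    for trait in traits:
        tslice = cm[cm["trait"] == trait]
        for day in days:
            dslice = tslice[tslice["day"] == day]
            if dslice.empty:
                continue
            try:
                fits[(trait, int(day))] = fit_day_trait(
                    dslice, trait=trait, day=int(day), covariate=covariate,
                    compute_se=compute_se, pooled_residual=pooled_residual,
                )
            except SingularDesignError:
                continue
    return FitSurface(fits)


def analyze_postharvest(
    ph: pd.DataFrame, compute_se: bool = True
) -> pd.DataFrame:
    """Summary of the post-harvest traits under the same bivariate model.

    Plants play the replicate role that carriers play for in-time traits.
    Returns one row per trait: -log10 p of the mean drought effect,
    genotype variance components per condition with standard errors, and
    genetic and phenotypic correlations between conditions.
    """
    rows = []
    for trait in sorted(ph["trait"].unique()):
        sub = ph[ph["trait"] == trait].rename(columns={"plant": "carrier"})
        fit = fit_day_trait(sub, trait=trait, compute_se=compute_se)
        rows.append({
            "trait": trait,
            "neglog10p": fit.neglog10p,
            "var_g_control": fit.var_g_control,
            "se_var_g_control": fit.se.get("var_g_control", np.nan),
            "var_g_drought": fit.var_g_drought,
            "se_var_g_drought": fit.se.get("var_g_drought", np.nan),
            "genetic_correlation": fit.genetic_correlation,
            "phenotypic_correlation": phenotypic_correlation(sub),
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)
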