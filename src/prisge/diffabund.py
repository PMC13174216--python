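"""Negative-binomial GLM testing of count time courses.

The engine tests, per variant (or per construct), whether read counts in
a drug arm diverge from the vehicle arm over the harvest time course.
Counts y_ij are modelled as NB(mu_ij, alpha_i) with Var = mu + alpha*mu^2,
log link and a sample-specific offset log(s_j) from median-of-ratios
size factors:

    log mu_ij = log s_j + x_j . beta_i

The full design is {intercept, time, drug, drug:time}; the reduced
design drops the drug terms, so a likelihood-ratio test with 2 degrees
of freedom asks whether drug treatment changes abundance as a function
of time.  Dispersion is estimated by method-of-moments within design
groups, moderated toward a 1/mu trend by log-space shrinkage.  A
one-sided Wald test on the drug effect at the final harvest day provides
the enrichment direction, and its base-2 effect size is the log2FC used
in hit calling (FDR < threshold AND log2FC > 0).

False discovery control is available both as Benjamini-Hochberg on the
LRT p-values and as an empirical FDR calibrated on the synonymous
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ValidationError


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For rows with all-positive counts, s_j = median_i of
    c_ij / geomean_i(c_i.).  If no row is all-positive the estimator
    falls back to the rows positive in every sample of a maximal subset
    (per-row positive medians), with a warning.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("counts must be a 2-D matrix")
    positive = (arr > 0).all(axis=1)
    if positive.sum() == 0:
        import warnings

        warnings.warn(
            "no all-positive row; using positive-subset median-of-ratios",
            stacklevel=2,
        )
        log_arr = np.where(arr > 0, np.log(arr), np.nan)
        log_gm = np.nanmean(log_arr, axis=1)
        ratios = log_arr - log_gm[:, None]
        log_sf = np.nanmedian(ratios, axis=0)
    else:
        sub = arr[positive]
        log_gm = np.log(sub).mean(axis=1)
        log_sf = np.median(np.log(sub) - log_gm[:, None], axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return np.exp(log_sf)


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Full and reduced design matrices for one drug-vs-vehicle test."""

    sample_ids: list[str]
    full: np.ndarray
    reduced: np.ndarray
    full_names: list[str]
    reduced_names: list[str]
    t_final: float

    @property
    def df_test(self) -> int:
        return self.full.shape[1] - self.reduced.shape[1]

    def drug_contrast(self) -> np.ndarray:
        """Contrast giving the drug effect at the final harvest day."""
        c = np.zeros(self.full.shape[1])
        for i, name in enumerate(self.full_names):
            if name == "drug":
                c[i] = 1.0
            elif name == "drug:time":
                c[i] = self.t_final
            elif name.startswith("drug:day["):
                # factor-time mode: final-day interaction column
                if name == f"drug:day[{self.t_final:g}]":
                    c[i] = 1.0
        return c


def build_design(sheet_frame: pd.DataFrame, drug_arm: str, control_arm: str,
                 time_as_factor: bool = False) -> DesignSpec:
    """Design matrices for samples of one drug arm plus the vehicle arm.

    Continuous time (default): full = {1, time, drug, drug:time},
    reduced = {1, time}.  Factor time: day enters as dummy columns with
    the first harvest as reference.
    """
    df = sheet_frame[sheet_frame["arm"].isin([drug_arm, control_arm])].copy()
    if df.empty:
        raise ValidationError(f"no samples for arms {drug_arm!r}/{control_arm!r}")
    df["day"] = df["day"].astype(float)
    df = df.sort_values(["arm", "day", "replicate"], kind="stable")
    time = df["day"].to_numpy()
    drug = (df["arm"] == drug_arm).to_numpy(dtype=float)
    t_final = float(time.max())
    if not time_as_factor:
        full = np.column_stack([np.ones_like(time), time, drug, drug * time])
        reduced = np.column_stack([np.ones_like(time), time])
        full_names = ["intercept", "time", "drug", "drug:time"]
        reduced_names = ["intercept", "time"]
    else:
        days = sorted(set(time))
        dummies = [(time == d).astype(float) for d in days[1:]]
        full_cols = [np.ones_like(time)] + dummies + [drug] + [
            drug * dm for dm in dummies
        ]
        full = np.column_stack(full_cols)
        reduced = np.column_stack([np.ones_like(time)] + dummies)
        full_names = (
            ["intercept"]
            + [f"day[{d:g}]" for d in days[1:]]
            + ["drug"]
            + [f"drug:day[{d:g}]" for d in days[1:]]
        )
        reduced_names = ["intercept"] + [f"day[{d:g}]" for d in days[1:]]
    return DesignSpec(
        sample_ids=list(df["sample_id"]),
        full=full,
        reduced=reduced,
        full_names=full_names,
        reduced_names=reduced_names,
        t_final=t_final,
    )


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    base_mean: np.ndarray
    alpha_raw: np.ndarray
    trend_params: tuple[float, float]
    alpha_final: np.ndarray
    shrink_weight: float

    def trend(self, mu: np.ndarray) -> np.ndarray:
        a0, a1 = self.trend_params
        return a0 / np.maximum(mu, 1e-12) + a1


def _group_labels(X: np.ndarray) -> np.ndarray:
    """Integer label per sample for each unique design row."""
    _, labels = np.unique(X, axis=0, return_inverse=True)
    return labels


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    sf: np.ndarray,
    design: DesignSpec,
    prior_df: float = 60.0,
) -> DispersionModel:
    """Moderated method-of-moments dispersion per unit.

    Raw per-unit estimate: within each group of samples sharing a design
    row, alpha_hat pools (s^2 - mu)/mu^2 on size-factor-scaled counts.
    A robust 1/mu + constant trend is fitted across units, and final
    dispersions shrink the raw estimate toward the trend in log space
    with weight df / (df + prior_df).  The default prior is wide: with
    triplicate groups the raw moment estimator is mostly noise, and a
    likelihood-ratio test run on under-shrunk dispersions is visibly
    anti-conservative; the trend carries most of the information.
    """
    arr = np.asarray(counts, dtype=float)
    scaled = arr / sf[None, :]
    labels = _group_labels(design.full)
    n_groups = len(np.unique(labels))
    n = arr.shape[1]
    resid_df = n - n_groups
    if resid_df < 2:
        raise InsufficientDataError("need >= 2 residual degrees of freedom")

    num = np.zeros(arr.shape[0])
    den = np.zeros(arr.shape[0])
    wsum = 0.0
    for g in np.unique(labels):
        cols = labels == g
        ng = int(cols.sum())
        if ng < 2:
            continue
        mu_g = scaled[:, cols].mean(axis=1)
        var_g = scaled[:, cols].var(axis=1, ddof=1)
        w = ng - 1
        num += w * (var_g - mu_g)
        # E[mu_g^2] = mu^2 + var/ng: debias the squared group mean
        den += w * np.maximum(mu_g**2 - var_g / ng, 1e-12)
        wsum += w
    alpha_unclipped = num / den
    alpha_raw = np.maximum(alpha_unclipped, 0.0)
    base_mean = scaled.mean(axis=1)

    usable = base_mean > 0
    if usable.sum() >= 10:
        # fit the trend on the unclipped estimates: zero-clipping would
        # bias the fitted trend upward, asymmetric trimming downward
        x = 1.0 / base_mean[usable]
        y = alpha_unclipped[usable]
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        mad = np.median(np.abs(resid - np.median(resid))) + 1e-12
        keep = np.abs(resid - np.median(resid)) <= 5.0 * mad
        if keep.sum() >= 10:
            coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 1e-8))
    else:
        pos = alpha_raw[alpha_raw > 0]
        a0 = 0.0
        a1 = max(float(np.median(pos)) if pos.size else 1e-8, 1e-8)

    trend = a0 / np.maximum(base_mean, 1e-12) + a1
    w = resid_df / (resid_df + prior_df)
    raw_floored = np.where(alpha_raw > 0, alpha_raw, trend)
    alpha_final = np.exp(
        w * np.log(np.maximum(raw_floored, 1e-10)) + (1 - w) * np.log(trend)
    )
    alpha_final = np.where(base_mean > 0, alpha_final, np.nan)
    return DispersionModel(
        base_mean=base_mean,
        alpha_raw=alpha_raw,
        trend_params=(a0, a1),
        alpha_final=alpha_final,
        shrink_weight=float(w),
    )


# ---------------------------------------------------------------------------
# NB GLM fit
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    beta: np.ndarray
    mu: np.ndarray
    alpha: float
    loglik: float
    converged: bool
    iterations: int
    X: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)

    def cov_beta(self) -> np.ndarray:
        XtWX = self.X.T @ (self.X * self.weights[:, None])
        return np.linalg.pinv(XtWX)


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (alpha = 0 degenerates to Poisson)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    sf: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 100,
    debug_monotone: bool = False,
) -> NBFit:
    """Fit one NB GLM by iteratively reweighted least squares.

    Log link with offset log(s_j); Fisher-scoring weights
    w = mu / (1 + alpha * mu); step-halving guards the likelihood
    ascent.  Convergence on relative deviance (log-likelihood) change
    below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("length of y must match rows of X")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design columns are linearly dependent")
    offset = np.log(sf)

    # initialize from a log-linear least squares fit
    z0 = np.log((y + 0.5) / sf)
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    ll = nb_loglik(y, mu, alpha)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        # step-halving: never let the log-likelihood decrease
        ll_new = -np.inf
        for _ in range(20):
            cand = beta + step
            eta_c = X @ cand + offset
            mu_c = np.exp(np.clip(eta_c, -30, 30))
            ll_new = nb_loglik(y, mu_c, alpha)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        if debug_monotone:
            assert ll_new >= ll - 1e-9, "likelihood decreased during IRLS"
        beta = beta + step
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        delta = abs(ll_new - ll) / (abs(ll) + 0.1)
        ll = ll_new
        if delta < tol:
            converged = True
            break
    w = mu / (1.0 + alpha * mu)
    return NBFit(
        beta=beta,
        mu=mu,
        alpha=float(alpha),
        loglik=ll,
        converged=converged,
        iterations=it,
        X=X,
        weights=w,
    )


def nb_loglik_optimum_oracle(
    y: np.ndarray, X: np.ndarray, sf: np.ndarray, alpha: float
) -> float:
    """Maximum NB log-likelihood found by a general-purpose optimizer.

    Independent check on the IRLS fitter: Nelder-Mead refinement of a
    BFGS solution on the negative log-likelihood.
    """
    offset = np.log(np.asarray(sf, dtype=float))
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    def neg_ll(beta):
        mu = np.exp(np.clip(X @ beta + offset, -30, 30))
        return -nb_loglik(y, mu, alpha)

    beta0, *_ = np.linalg.lstsq(X, np.log((y + 0.5) / np.asarray(sf)), rcond=None)
    res = optimize.minimize(neg_ll, beta0, method="BFGS")
    res2 = optimize.minimize(neg_ll, res.x, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12})
    return float(-min(res.fun, res2.fun))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def lrt(full: NBFit, reduced: NBFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested NB fits sharing one dispersion."""
    if full.alpha != reduced.alpha:
        raise ValidationError("full and reduced fits must share the dispersion")
    df = full.X.shape[1] - reduced.X.shape[1]
    if df < 0:
        raise ValidationError("reduced design must be nested in the full design")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return stat, 0, 1.0
    p = float(chi2.sf(stat, df))
    return stat, df, p


def wald_one_sided(fit: NBFit, contrast: np.ndarray) -> tuple[float, float]:
    """One-sided (enrichment) Wald test of a coefficient contrast.

    stat = c.beta / SE(c.beta) with SE from the Fisher information at
    the optimum; p is the upper normal tail.
    """
    c = np.asarray(contrast, dtype=float)
    cov = fit.cov_beta()
    var = float(c @ cov @ c)
    if var <= 0 or not np.isfinite(var):
        return float("nan"), float("nan")
    stat = float(c @ fit.beta) / np.sqrt(var)
    return stat, float(norm.sf(stat))


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def empirical_fdr(p, is_control, min_controls: int = 10) -> np.ndarray:
    """Empirical FDR calibrated on the control units.

    At threshold t = p_i,
    efdr_i = min(1, (#controls <= t / N_controls) * N_tested
                     / max(1, #units <= t)),
    monotonized by a cumulative minimum from the largest p down.
    NaN p-values propagate.
    """
    p = np.asarray(p, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    if p.shape != is_control.shape:
        raise ValidationError("p and is_control must have the same length")
    ok = np.isfinite(p)
    n_controls = int((is_control & ok).sum())
    if n_controls < min_controls:
        raise InsufficientDataError(
            f"only {n_controls} controls (< {min_controls}); use BH-only mode"
        )
    out = np.full_like(p, np.nan)
    pv = p[ok]
    ctrl = is_control[ok]
    n_tested = pv.size
    order = np.argsort(pv, kind="stable")
    sorted_p = pv[order]
    ctrl_sorted = ctrl[order]
    # ties: every unit at a tied p shares the count at the tie's right edge
    n_le = np.searchsorted(sorted_p, sorted_p, side="right")
    ctrl_cum = np.cumsum(ctrl_sorted)
    ctrl_le = ctrl_cum[n_le - 1]
    efdr = np.minimum(1.0, (ctrl_le / n_controls) * n_tested / np.maximum(1, n_le))
    efdr = np.minimum.accumulate(efdr[::-1])[::-1]
    vals = np.empty_like(efdr)
    vals[order] = efdr
    out[ok] = vals
    return out


def call_hits(
    results: pd.DataFrame,
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 0.0,
    fdr_column: str = "efdr",
) -> pd.DataFrame:
    """Flag hits: selected FDR below threshold AND model log2FC above
    threshold (depleted units are never hits)."""
    out = results.copy()
    if out.empty:
        out["hit"] = pd.Series(dtype=bool)
        return out
    fdr_vals = out[fdr_column]
    out["hit"] = (fdr_vals < fdr_threshold) & (out["log2fc_model"] > lfc_threshold)
    out.loc[fdr_vals.isna() | out["log2fc_model"].isna(), "hit"] = False
    return out
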