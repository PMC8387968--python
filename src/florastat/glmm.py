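"""Binomial random-intercept model of species-level identification success.

The outcome is binary — was the first suggestion the correct species? — and
the fixed effects are the three image annotations (organs, focus,
background) under treatment coding with alphabetically first reference
levels.  A per-species Gaussian random intercept absorbs the strong
between-species differences; only species with at least ``min_obs``
observations enter the fit.

Estimation maximizes the marginal likelihood with a Laplace approximation
to the random-effect integral.  For a species ``s`` with observations
``(y_i, x_i)`` the contribution is

    ∫ ∏_i Bernoulli(y_i | logit⁻¹(x_iᵝ + u)) · N(u | 0, σ²) du
      ≈ exp(h(u*)) / sqrt(1 + σ² W(u*)),

where ``h`` collects the Bernoulli log-likelihood plus the Gaussian penalty,
``u*`` is the per-species mode (found by a damped Newton step, the problem
is strictly concave in ``u``) and ``W`` the summed Bernoulli weights at the
mode.  The outer optimization over (β, log σ) uses L-BFGS-B; the fixed-effect
covariance matrix is the corresponding block of the inverse numerical
Hessian of the negative marginal log-likelihood.

Inference helpers mirror the standard mixed-model workflow: type III Wald
chi-square tests per factor, estimated marginal means (equal weights over
the other factors' levels, random effect at zero), pairwise z contrasts with
Holm adjustment, and a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtr
from scipy.stats import chi2

from .data_model import IdentificationClass
from .errors import ValidationError

logger = logging.getLogger("florastat")

__all__ = ["GLMMFit", "EMMResult", "fit_binary_mixed", "type3_wald",
           "estimated_marginal_means", "compact_letter_display"]

DEFAULT_FACTORS = ("organs", "focus", "background")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _build_design(df: pd.DataFrame, factors) -> tuple[np.ndarray, list[str],
                                                      dict, dict]:
    """Treatment-coded design matrix with intercept.

    Returns (X, column names, factor -> levels, factor -> column indices).
    Factors with a single observed level are dropped with a warning.
    """
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    levels: dict[str, list[str]] = {}
    blocks: dict[str, list[int]] = {}
    for f in factors:
        lv = sorted(df[f].unique().tolist())
        if len(lv) < 2:
            logger.warning("factor %r has a single observed level %r; dropped",
                           f, lv)
            continue
        levels[f] = lv
        blocks[f] = []
        for l in lv[1:]:
            blocks[f].append(len(names))
            names.append(f"{f}[{l}]")
            cols.append((df[f] == l).to_numpy(float))
    return np.column_stack(cols), names, levels, blocks


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------


def _laplace_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                 g: np.ndarray, n_groups: int) -> float:
    p = X.shape[1]
    beta, log_sigma = theta[:p], theta[p]
    sigma2 = float(np.exp(2.0 * log_sigma))
    eta0 = X @ beta
    u = np.zeros(n_groups)
    inv_s2 = 1.0 / sigma2
    for _ in range(60):
        eta = eta0 + u[g]
        mu = expit(eta)
        s = np.bincount(g, weights=y - mu, minlength=n_groups)
        w = np.bincount(g, weights=mu * (1.0 - mu), minlength=n_groups)
        step = (s - u * inv_s2) / (w + inv_s2)
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[g]
    mu = expit(eta)
    w = np.bincount(g, weights=mu * (1.0 - mu), minlength=n_groups)
    ll_obs = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    ll = (ll_obs
          - 0.5 * float(np.sum(u * u)) * inv_s2
          - 0.5 * float(np.sum(np.log1p(sigma2 * w))))
    return -ll


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class GLMMFit:
    """Fitted binomial random-intercept model."""

    coef: pd.Series                       # fixed effects, logit scale
    cov: pd.DataFrame                     # their covariance matrix
    sigma_u: float                        # random-intercept SD
    factor_levels: dict[str, list[str]]
    factor_blocks: dict[str, list[int]]   # coef indices per factor
    reference: dict[str, str]
    n_obs_used: int
    n_species_used: int
    loglik: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def coef_names(self) -> list[str]:
        return list(self.coef.index)


def fit_binary_mixed(observations: pd.DataFrame, min_obs: int = 3,
                     factors=DEFAULT_FACTORS) -> GLMMFit:
    """Fit the species-success GLMM by Laplace-approximate ML.

    ``observations`` needs ``class_code``, ``verified_name`` and the factor
    columns.  Species with fewer than ``min_obs`` observations are excluded
    before fitting.  Non-convergence is flagged on the result (with the
    optimizer message in ``diagnostics``), never silent.
    """
    counts = observations["verified_name"].value_counts()
    keep = counts.index[counts >= min_obs]
    df = observations[observations["verified_name"].isin(keep)]
    if df.empty:
        raise ValidationError(
            f"no species has >= {min_obs} observations; nothing to fit")
    # canonical row order: estimates must not depend on input permutation
    df = df.sort_values(["verified_name", *factors, "class_code"],
                        kind="stable")
    y = (df["class_code"].to_numpy() == int(IdentificationClass.SPECIES)
         ).astype(float)
    X, names, levels, blocks = _build_design(df, factors)
    sp, g = np.unique(df["verified_name"].to_numpy(object), return_inverse=True)
    n_groups = sp.size

    # plain logistic fit (ignoring the grouping) as a starting point
    import statsmodels.api as sm
    start = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
    x0 = np.concatenate([start.params, [np.log(0.5)]])

    nll = lambda th: _laplace_nll(th, X, y, g, n_groups)
    p = X.shape[1]
    bounds = [(None, None)] * p + [(-5.0, 2.5)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 300, "ftol": 1e-11})
    theta = res.x
    sigma_u = float(np.exp(theta[p]))

    H = _numeric_hessian(nll, theta)
    H = 0.5 * (H + H.T)
    # the observed information must be PSD; flat directions (separation,
    # sigma at its boundary) get their curvature floored, which inflates the
    # corresponding variances instead of producing a broken matrix
    w, Q = np.linalg.eigh(H)
    floor = 1e-6 * max(float(w.max()), 1.0)
    flat = w < floor
    if flat.any():
        logger.warning("information matrix has %d flat direction(s); "
                       "their curvature floored", int(flat.sum()))
    w = np.maximum(w, floor)
    cov_full = (Q / w) @ Q.T
    cov_beta = 0.5 * (cov_full[:p, :p] + cov_full[:p, :p].T)

    fit = GLMMFit(
        coef=pd.Series(theta[:p], index=names),
        cov=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma_u=sigma_u,
        factor_levels=levels,
        factor_blocks=blocks,
        reference={f: lv[0] for f, lv in levels.items()},
        n_obs_used=int(len(df)),
        n_species_used=int(n_groups),
        loglik=-float(res.fun),
        converged=bool(res.success),
        diagnostics={"message": str(res.message), "n_iter": int(res.nit),
                     "boundary_sigma": sigma_u <= np.exp(-5.0) * 1.01},
    )
    if not res.success:
        logger.warning("GLMM optimizer did not report convergence: %s",
                       res.message)
    return fit


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def type3_wald(fit: GLMMFit) -> pd.DataFrame:
    """Type III Wald chi-square test per factor: the factor's coefficient
    block ``b`` against zero, chisq = bᵀ V_b⁻¹ b, df = block size."""
    rows = []
    V = fit.cov.to_numpy()
    b_all = fit.coef.to_numpy()
    for f, idx in fit.factor_blocks.items():
        b = b_all[idx]
        Vb = V[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(Vb, b))
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                f"singular covariance block for factor {f!r}") from exc
        df_ = len(idx)
        rows.append({"factor": f, "chisq": stat, "df": df_,
                     "p_value": float(chi2.sf(stat, df_))})
    return pd.DataFrame(rows)


def _emm_vector(fit: GLMMFit, factor: str, level: str) -> np.ndarray:
    """Linear combination giving the EMM of ``level``: equal-weight average
    of the linear predictor over the other factors' levels, random effect 0."""
    c = np.zeros(len(fit.coef))
    c[0] = 1.0
    for f, lv in fit.factor_levels.items():
        if f == factor:
            if level != lv[0]:
                c[fit.factor_blocks[f][lv[1:].index(level)]] = 1.0
        else:
            for pos, l in zip(fit.factor_blocks[f], lv[1:]):
                c[pos] = 1.0 / len(lv)
    return c


@dataclass
class EMMResult:
    """Estimated marginal means for one factor with pairwise contrasts."""

    factor: str
    levels: list[str]
    emm_logit: dict[str, float]
    se: dict[str, float]
    prob: dict[str, float]
    contrasts: pd.DataFrame     # level_1, level_2, estimate, se, z, p, p_holm
    letters: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.factor,
            "level": self.levels,
            "emm_logit": [self.emm_logit[l] for l in self.levels],
            "prob": [self.prob[l] for l in self.levels],
            "se_logit": [self.se[l] for l in self.levels],
            "letters": [self.letters.get(l, "") for l in self.levels],
        })


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals, kind="stable")
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def estimated_marginal_means(fit: GLMMFit, factor: str,
                             alpha: float = 0.05) -> EMMResult:
    """EMMs of ``factor`` with delta-method SEs, Holm-adjusted pairwise z
    contrasts on the logit scale, and compact letters at level ``alpha``."""
    if factor not in fit.factor_levels:
        raise ValidationError(f"factor {factor!r} not in the fitted model")
    levels = fit.factor_levels[factor]
    V = fit.cov.to_numpy()
    beta = fit.coef.to_numpy()
    vectors = {l: _emm_vector(fit, factor, l) for l in levels}
    emm = {l: float(vectors[l] @ beta) for l in levels}
    se = {l: float(np.sqrt(vectors[l] @ V @ vectors[l])) for l in levels}
    prob = {l: float(expit(emm[l])) for l in levels}

    pairs = list(itertools.combinations(levels, 2))
    est, ses, zs, ps = [], [], [], []
    for l1, l2 in pairs:
        d = vectors[l1] - vectors[l2]
        de = float(d @ beta)
        sd = float(np.sqrt(d @ V @ d))
        z = de / sd if sd > 0 else 0.0
        est.append(de); ses.append(sd); zs.append(z)
        ps.append(float(2.0 * (1.0 - ndtr(abs(z)))))
    p_adj = _holm(np.asarray(ps)) if pairs else np.array([])
    contrasts = pd.DataFrame({
        "level_1": [a for a, _ in pairs], "level_2": [b for _, b in pairs],
        "estimate": est, "se": ses, "z": zs, "p": ps, "p_holm": p_adj,
    })
    result = EMMResult(factor=factor, levels=levels, emm_logit=emm, se=se,
                       prob=prob, contrasts=contrasts)
    result.letters = compact_letter_display(result, alpha=alpha)
    return result


def compact_letter_display(emm, alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb letter coding of the pairwise comparisons.

    Levels that share no letter differ significantly (Holm-adjusted
    ``p < alpha``); levels sharing at least one letter do not.  Accepts an
    :class:`EMMResult` or a tuple ``(levels, contrasts_frame)`` where the
    frame has columns level_1, level_2 and p_holm (or p).
    """
    if isinstance(emm, EMMResult):
        levels, contrasts = emm.levels, emm.contrasts
    else:
        levels, contrasts = emm
    pcol = "p_holm" if "p_holm" in contrasts.columns else "p"
    sig_pairs = [
        (str(r.level_1), str(r.level_2))
        for r in contrasts.itertuples()
        if getattr(r, pcol) < alpha
    ]
    sets: list[set[str]] = [set(levels)]
    for a, b in sig_pairs:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: deduplicate, then drop sets strictly contained in another
        uniq: list[set[str]] = []
        for s in new_sets:
            if s and s not in uniq:
                uniq.append(s)
        sets = [s for s in uniq if not any(s < t for t in uniq)]
    sets.sort(key=lambda s: min(levels.index(l) for l in s))
    letters = {l: "" for l in levels}
    for k, s in enumerate(sets):
        ch = chr(ord("a") + k)
        for l in s:
            letters[l] += ch
    return letters
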