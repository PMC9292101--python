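"""Behavioral analysis of 2AFC word-learning responses.

The central model is a binomial generalized linear mixed model with a logit
link: trial-level correctness is predicted by Condition (passive listening
vs articulatory suppression), Group (high vs low synchronizer) and their
interaction as fixed effects, with a random intercept per participant.
Factors are coded sum-to-zero (+/- 0.5), so main-effect coefficients are
average cell-mean differences and likelihood-ratio tests of single terms
have the Type-3 interpretation.

The marginal likelihood integrates the random intercept out numerically:
the default is the Laplace approximation (one mode + curvature per
participant); adaptive Gauss-Hermite quadrature with any node count is
available and serves as the accuracy oracle in the test suite.

Also here: estimated marginal means and pairwise contrasts on the logit
scale (delta-method SEs), Wilcoxon tests against chance (50%), and the
shared nonparametric/FDR utilities used throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats
from scipy.special import expit, gammaln
from statsmodels.stats.multitest import multipletests

TERMS = ("intercept", "condition", "group", "interaction")
_CODES = {"PL": 0.5, "AS": -0.5, "high": 0.5, "low": -0.5}


@dataclass
class MixedModelFit:
    """Fitted binomial random-intercept mixed model."""

    fixed_effects: dict[str, float]
    re_sd: float
    loglik: float
    aic: float
    vcov: np.ndarray
    terms: tuple[str, ...]
    n_participants: int
    n_obs: int
    converged: bool
    singular: bool = False
    separation: bool = False
    method: str = "laplace"

    @property
    def re_variance(self) -> float:
        return self.re_sd**2


@dataclass(frozen=True)
class EffectTest:
    term: str
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class MarginalContrast:
    contrast: str
    estimate: float
    se: float
    zratio: float
    p: float
    response_means: dict


def _aggregate(data: pd.DataFrame) -> pd.DataFrame:
    """Collapse trial rows to per participant x condition binomial counts."""
    g = (
        data.groupby(["participant", "group", "condition"], sort=True)["correct"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    g["c"] = g["condition"].map(_CODES)
    g["g"] = g["group"].map(_CODES)
    return g


def _design(agg: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = {
        "intercept": np.ones(len(agg)),
        "condition": agg["c"].to_numpy(),
        "group": agg["g"].to_numpy(),
        "interaction": (agg["c"] * agg["g"]).to_numpy(),
    }
    return np.column_stack([cols[t] for t in terms])


class _LaplaceObjective:
    """Marginal log-likelihood of the binomial random-intercept model.

    Observations are pre-aggregated binomial counts.  For participant i with
    linear predictors eta_ij + b and prior b ~ N(0, sigma^2), the integrand
    mode is found by vectorized Newton steps across all participants at once;
    the marginal likelihood is then either the Laplace approximation at the
    mode or adaptive Gauss-Hermite quadrature centered/scaled at the mode.
    """

    def __init__(self, agg: pd.DataFrame, terms: tuple[str, ...], agq: int = 1):
        self.X = _design(agg, terms)
        self.y = agg["successes"].to_numpy(float)
        self.n = agg["trials"].to_numpy(float)
        codes, self.pidx = np.unique(agg["participant"], return_inverse=True)
        self.n_participants = len(codes)
        self.agq = agq
        self.const = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1))
        )
        if agq > 1:
            x, w = hermegauss(agq)  # probabilists' Hermite: weight e^{-x^2/2}
            self.gh_x, self.gh_logw = x, np.log(w)

    def _sums(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_participants)
        np.add.at(out, self.pidx, v)
        return out

    def _mode(self, eta0: np.ndarray, sigma2: float) -> tuple[np.ndarray, np.ndarray]:
        b = np.zeros(self.n_participants)
        for _ in range(50):
            eta = eta0 + b[self.pidx]
            p = expit(eta)
            grad = self._sums(self.y - self.n * p) - b / sigma2
            hess = -self._sums(self.n * p * (1 - p)) - 1.0 / sigma2
            step = grad / hess
            b_new = b - step
            if np.max(np.abs(step)) < 1e-10:
                b = b_new
                break
            b = b_new
        eta = eta0 + b[self.pidx]
        p = expit(eta)
        hess = -self._sums(self.n * p * (1 - p)) - 1.0 / sigma2
        return b, hess

    def _cond_loglik(self, eta: np.ndarray) -> np.ndarray:
        # sum over cells of y*eta - n*log(1+e^eta), grouped by participant
        return self._sums(self.y * eta - self.n * np.logaddexp(0.0, eta))

    def loglik(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        sigma2 = sigma**2
        eta0 = self.X @ beta
        b_hat, hess = self._mode(eta0, sigma2)
        if self.agq <= 1:
            g = (
                self._cond_loglik(eta0 + b_hat[self.pidx])
                - 0.5 * b_hat**2 / sigma2
                - 0.5 * np.log(2 * np.pi * sigma2)
            )
            ll = np.sum(g + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(-hess))
        else:
            s = 1.0 / np.sqrt(-hess)  # (participants,)
            nodes = b_hat[:, None] + s[:, None] * self.gh_x[None, :]
            g = np.empty_like(nodes)
            for k in range(nodes.shape[1]):
                bk = nodes[:, k]
                g[:, k] = (
                    self._cond_loglik(eta0 + bk[self.pidx])
                    - 0.5 * bk**2 / sigma2
                    - 0.5 * np.log(2 * np.pi * sigma2)
                )
            # int e^g db = s * sum_k w_k e^{x_k^2/2} g(node_k)  (Hermite_e weights)
            expo = g + self.gh_logw[None, :] + 0.5 * self.gh_x[None, :] ** 2
            m = expo.max(axis=1)
            ll = float(
                np.sum(np.log(s) + m + np.log(np.sum(np.exp(expo - m[:, None]), axis=1)))
            )
        return float(ll) + self.const

    def __call__(self, params: np.ndarray) -> float:
        return -self.loglik(params)


class _MultiLaplaceObjective:
    """Joint Laplace marginal likelihood with several random-intercept factors.

    Used when language/block-order random intercepts are added to the
    participant intercept: the joint mode of all random effects is found by
    dense Newton (the total number of levels is small) and the marginal
    likelihood approximated at the mode.  One variance parameter per factor.
    """

    def __init__(self, data: pd.DataFrame, terms: tuple[str, ...],
                 factors: tuple[str, ...],
                 cell_factors: tuple[str, ...] | None = None):
        cols = ["participant", "group", "condition"] + [
            f for f in (cell_factors or factors) if f not in ("participant",)
        ]
        g = (
            data.groupby(cols, sort=True)["correct"]
            .agg(successes="sum", trials="count")
            .reset_index()
        )
        g["c"] = g["condition"].map(_CODES)
        g["g"] = g["group"].map(_CODES)
        self.X = _design(g, terms)
        self.y = g["successes"].to_numpy(float)
        self.n = g["trials"].to_numpy(float)
        self.factors = factors
        self.blocks = []  # (slice in b, level index per obs)
        q = 0
        for f in factors:
            levels, idx = np.unique(g[f], return_inverse=True)
            self.blocks.append((slice(q, q + len(levels)), idx))
            q += len(levels)
        self.q = q
        self.Z = np.zeros((len(g), q))
        for sl, idx in self.blocks:
            self.Z[np.arange(len(g)), sl.start + idx] = 1.0
        self.const = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1))
        )

    def loglik(self, params: np.ndarray) -> float:
        nb = self.X.shape[1]
        beta = params[:nb]
        sigmas = np.exp(params[nb:])
        d_inv = np.zeros(self.q)
        for (sl, _), s in zip(self.blocks, sigmas):
            d_inv[sl] = 1.0 / max(s**2, 1e-12)
        eta0 = self.X @ beta
        b = np.zeros(self.q)
        for _ in range(100):
            eta = eta0 + self.Z @ b
            p = expit(eta)
            grad = self.Z.T @ (self.y - self.n * p) - d_inv * b
            w = self.n * p * (1 - p)
            hess = -(self.Z.T * w) @ self.Z - np.diag(d_inv)
            step = np.linalg.solve(hess, grad)
            b = b - step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = eta0 + self.Z @ b
        p = expit(eta)
        w = self.n * p * (1 - p)
        hess = -(self.Z.T * w) @ self.Z - np.diag(d_inv)
        cond_ll = float(np.sum(self.y * eta - self.n * np.logaddexp(0.0, eta)))
        log_prior = float(-0.5 * np.sum(d_inv * b**2) + 0.5 * np.sum(np.log(d_inv))
                          - 0.5 * self.q * np.log(2 * np.pi))
        sign, logdet = np.linalg.slogdet(-hess)
        return (cond_ll + log_prior + 0.5 * self.q * np.log(2 * np.pi)
                - 0.5 * logdet + self.const)

    def __call__(self, params: np.ndarray) -> float:
        return -self.loglik(params)


def fit_binomial_glmm(
    data: pd.DataFrame,
    terms: tuple[str, ...] = TERMS,
    method: str = "laplace",
    agq_points: int = 25,
    extra_random: tuple[str, ...] = (),
) -> MixedModelFit:
    """Fit the binomial logit mixed model with a participant random intercept.

    ``terms`` selects the fixed effects (subset of intercept/condition/group/
    interaction); ``method`` is "laplace" (default, matching the lme4/glmer
    convention) or "agq" with ``agq_points`` quadrature nodes.  Additional
    random-intercept factors (columns of ``data`` such as "language" or
    "block_order") may be listed in ``extra_random``; they are off by default
    and force the joint-Laplace path.
    """
    if extra_random:
        return _fit_multi(data, terms, ("participant",) + tuple(extra_random))
    agg = _aggregate(data)
    if agg.groupby("group")["participant"].nunique().min() < 2 and "group" in terms:
        raise ValueError("need at least 2 participants per group")
    if agg["condition"].nunique() < 2 and "condition" in terms:
        raise ValueError("both conditions must be present")
    separation = bool(
        (agg.groupby(["group", "condition"])
         .apply(lambda d: d["successes"].sum() in (0, d["trials"].sum()),
                include_groups=False))
        .any()
    )
    if separation:
        warnings.warn("complete separation in at least one design cell; "
                      "coefficients may be unstable", RuntimeWarning)

    obj = _LaplaceObjective(agg, terms, agq=agq_points if method == "agq" else 1)
    # start from the pooled logistic regression
    p0 = (agg["successes"].sum() + 0.5) / (agg["trials"].sum() + 1.0)
    x0 = np.zeros(len(terms) + 1)
    if "intercept" in terms:
        x0[terms.index("intercept")] = np.log(p0 / (1 - p0))
    x0[-1] = np.log(0.5)
    bounds = [(None, None)] * len(terms) + [(-8.0, 4.0)]
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    params = res.x
    ll = obj.loglik(params)
    k = len(terms) + 1
    vcov = _fixed_vcov(obj, params, len(terms))
    sigma = float(np.exp(params[-1]))
    singular = params[-1] <= bounds[-1][0] + 1e-6 or sigma < 1e-3
    return MixedModelFit(
        fixed_effects={t: float(b) for t, b in zip(terms, params[:-1])},
        re_sd=0.0 if singular else sigma,
        loglik=float(ll),
        aic=2 * k - 2 * float(ll),
        vcov=vcov,
        terms=tuple(terms),
        n_participants=obj.n_participants,
        n_obs=int(obj.n.sum()),
        converged=bool(res.success),
        singular=singular,
        separation=separation,
        method=method,
    )


def _fit_multi(data: pd.DataFrame, terms: tuple[str, ...],
               factors: tuple[str, ...],
               cell_factors: tuple[str, ...] | None = None) -> MixedModelFit:
    obj = _MultiLaplaceObjective(data, terms, factors, cell_factors)
    x0 = np.zeros(len(terms) + len(factors))
    x0[len(terms):] = np.log(0.5)
    bounds = [(None, None)] * len(terms) + [(-8.0, 4.0)] * len(factors)
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    ll = obj.loglik(res.x)
    k = len(terms) + len(factors)
    sigmas = np.exp(res.x[len(terms):])
    return MixedModelFit(
        fixed_effects={t: float(b) for t, b in zip(terms, res.x[:len(terms)])},
        re_sd=float(sigmas[0]) if sigmas[0] >= 1e-3 else 0.0,
        loglik=float(ll),
        aic=2 * k - 2 * float(ll),
        vcov=_fixed_vcov(obj, res.x, len(terms)),
        terms=tuple(terms),
        n_participants=data["participant"].nunique(),
        n_obs=len(data),
        converged=bool(res.success),
        singular=bool(np.any(sigmas < 1e-3)),
        method="laplace-joint",
    )


def _fixed_vcov(obj, params: np.ndarray, n_beta: int) -> np.ndarray:
    """Observed-information covariance of the fixed effects (numerical Hessian)."""
    n = len(params)
    h = 1e-4 * np.maximum(1.0, np.abs(params))
    hess = np.zeros((n, n))
    f0 = obj(params)
    for i in range(n):
        for j in range(i, n):
            pp = params.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = params.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = params.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = params.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            hess[i, j] = hess[j, i] = (
                obj(pp) - obj(pm) - obj(mp) + obj(mm)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return cov[:n_beta, :n_beta]


def compare_random_terms(
    data: pd.DataFrame,
    candidates: tuple[str, ...] = ("language",),
    terms: tuple[str, ...] = TERMS,
) -> dict[str, float]:
    """AIC change from adding each candidate random-intercept factor.

    For each candidate (e.g. "language", "block_order") the base model
    (participant intercept only) and the extended model are fitted on cells
    aggregated identically, so their likelihood constants cancel.  Returns
    {candidate: AIC_extended - AIC_base}; positive values favor the base
    model, mirroring the keep-it-simple selection rule.
    """
    out = {}
    for cand in candidates:
        base = _fit_multi(data, terms, ("participant",), cell_factors=("participant", cand))
        ext = _fit_multi(data, terms, ("participant", cand))
        out[cand] = float(ext.aic - base.aic)
    return out


def type3_lr_tests(
    data: pd.DataFrame,
    terms: tuple[str, ...] = TERMS,
    method: str = "laplace",
) -> list[EffectTest]:
    """Type-3 likelihood-ratio tests of each non-intercept term.

    Under sum-to-zero coding each term is dropped alone from the full model
    (main effects are tested with the interaction retained), and
    chi2 = 2 (loglik_full - loglik_reduced) with df = columns dropped.
    """
    full = fit_binomial_glmm(data, terms, method=method)
    out = []
    for term in terms:
        if term == "intercept":
            continue
        reduced_terms = tuple(t for t in terms if t != term)
        red = fit_binomial_glmm(data, reduced_terms, method=method)
        chi2 = max(0.0, 2 * (full.loglik - red.loglik))
        df = 1
        out.append(EffectTest(term=term, chi2=float(chi2), df=df,
                              p=float(stats.chi2.sf(chi2, df))))
    return out


_CONTRASTS = {
    # L vectors over (intercept, condition, group, interaction), +/-0.5 coding
    "PL-AS | high": np.array([0.0, 1.0, 0.0, 0.5]),
    "PL-AS | low": np.array([0.0, 1.0, 0.0, -0.5]),
    "high-low | PL": np.array([0.0, 0.0, 1.0, 0.5]),
    "high-low | AS": np.array([0.0, 0.0, 1.0, -0.5]),
}

_CELLS = {
    ("high", "PL"): np.array([1.0, 0.5, 0.5, 0.25]),
    ("high", "AS"): np.array([1.0, -0.5, 0.5, -0.25]),
    ("low", "PL"): np.array([1.0, 0.5, -0.5, -0.25]),
    ("low", "AS"): np.array([1.0, -0.5, -0.5, 0.25]),
}


def marginal_means(fit: MixedModelFit) -> pd.DataFrame:
    """Estimated marginal means of the four design cells, response scale."""
    beta = np.array([fit.fixed_effects[t] for t in fit.terms])
    rows = []
    for (group, cond), L in _CELLS.items():
        Lt = np.array([L[TERMS.index(t)] for t in fit.terms])
        est = float(Lt @ beta)
        se = float(np.sqrt(Lt @ fit.vcov @ Lt))
        rows.append({
            "group": group, "condition": cond,
            "logit": est, "se": se,
            "prob": float(expit(est)),
            "ci_lo": float(expit(est - 1.96 * se)),
            "ci_hi": float(expit(est + 1.96 * se)),
        })
    return pd.DataFrame(rows)


def marginal_contrasts(fit: MixedModelFit) -> list[MarginalContrast]:
    """Condition contrasts within group and group contrasts within condition.

    Estimates are logit-scale differences of estimated marginal means with
    delta-method standard errors from the fixed-effect covariance.
    """
    if not fit.converged:
        raise ValueError("cannot form contrasts from a non-converged fit")
    beta = np.array([fit.fixed_effects[t] for t in fit.terms])
    means = marginal_means(fit)
    out = []
    for name, L in _CONTRASTS.items():
        Lt = np.array([L[TERMS.index(t)] for t in fit.terms])
        est = float(Lt @ beta)
        se = float(np.sqrt(Lt @ fit.vcov @ Lt))
        z = est / se if se > 0 else np.inf * np.sign(est)
        out.append(MarginalContrast(
            contrast=name, estimate=est, se=se, zratio=float(z),
            p=float(2 * stats.norm.sf(abs(z))),
            response_means=means.to_dict("records"),
        ))
    return out


def chance_tests(data: pd.DataFrame, min_n: int = 6) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank tests of accuracy against 0.5 per cell."""
    acc = (
        data.groupby(["group", "condition", "participant"])["correct"]
        .mean()
        .reset_index(name="accuracy")
    )
    rows = []
    for (group, cond), d in acc.groupby(["group", "condition"]):
        a = d["accuracy"].to_numpy()
        if len(a) < min_n:
            raise ValueError(
                f"cell {group}/{cond} has {len(a)} participants; need >= {min_n}"
            )
        p = wilcoxon_signed(a, 0.5)
        rows.append({"group": group, "condition": cond, "n": len(a),
                     "median_accuracy": float(np.median(a)), "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared nonparametric / multiple-testing utilities


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value."""
    return float(stats.mannwhitneyu(np.asarray(a), np.asarray(b),
                                    alternative="two-sided").pvalue)


def wilcoxon_signed(a, mu0: float = 0.0) -> float:
    """Two-sided Wilcoxon signed-rank p-value against location ``mu0``.

    Exact null for n <= 25 (no ties/zeros), normal approximation with
    continuity/tie correction otherwise.
    """
    d = np.asarray(a, float) - mu0
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("signed-rank statistic undefined: all values equal mu0")
    method = "exact" if (len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)) else "approx"
    return float(stats.wilcoxon(d, alternative="two-sided", method=method,
                                correction=(method == "approx")).pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (r, two-sided p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("length mismatch in correlation inputs")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, float)
    return multipletests(p, method="fdr_bh")[1]
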