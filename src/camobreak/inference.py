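"""Mixed-model inference on detection times and wrong-side errors.

The analysis chain mirrors standard practice in visual-search
psychophysics.  Censoring-corrected cell mean RTs are modelled with normal
error and wrong-side error counts with binomial error and a logit link;
both models carry fixed effects of square size, treatment and their
interaction, and a per-subject random intercept.  All fits are by maximum
likelihood (never REML) so deviances are comparable across fixed-effect
structures; terms are tested by the change in deviance against a
chi-square distribution.  Treatment comparisons come in two families: the
a-priori simple contrasts of every treatment against the Border reference
(unadjusted) and the secondary all-pairs comparisons with a single-step
Tukey-type adjustment based on the joint normal distribution of the
contrast statistics.

The normal model is fit with statsmodels' MixedLM.  The binomial
random-intercept model is fit here by adaptive Gauss-Hermite quadrature
(Laplace-centred nodes), since no maximum-likelihood binomial GLMM is
available in the scientific Python stack; with default order 15 the
marginal likelihood is accurate well past the stability of the test
statistics built on it.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import patsy
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools import numdiff

from .scene import TREATMENTS

__all__ = [
    "ModelFit",
    "LrtResult",
    "OrderingSummary",
    "count_errors",
    "fit_mixed",
    "lrt",
    "contrasts_vs_reference",
    "tukey_pairwise",
    "ordering_summary",
    "anova_crosscheck",
    "analyse_experiment",
]

REFERENCE_TREATMENT = "Border"
TUKEY_MC_SEED = 20140128  # fixed so adjusted p-values are reproducible
TUKEY_MC_DRAWS = 100_000
_ALLOWED_TERMS = ("size", "treatment", "size:treatment")


@dataclass
class ModelFit:
    """A fitted one-random-intercept model (ML)."""

    response_kind: str  # normal_mean_rt | binomial_errors
    fixed_terms: tuple[str, ...]
    params: pd.Series
    cov: pd.DataFrame
    subject_intercept_variance: float
    log_likelihood: float
    n_obs: int
    design_info: object
    treatment_levels: tuple[str, ...]
    size_levels: tuple[str, ...]
    non_estimable_levels: frozenset = dc_field(default_factory=frozenset)
    notes: tuple[str, ...] = ()
    _cell_row_cache: dict | None = dc_field(default=None, repr=False, compare=False)

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    @property
    def n_fixed_params(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class LrtResult:
    term: str
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class OrderingSummary:
    """Treatment ordering by estimated mean, grouped at the given alpha."""

    groups: tuple[tuple[str, ...], ...]
    text: str
    overlapping: bool
    alpha: float

    def __str__(self) -> str:
        return self.text


def count_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Wrong-side error counts per subject x treatment x size cell.

    The denominator counts only trials where a response was made: a
    time-out is a different (and rare) class of failure from a wrong
    decision, so censored trials never enter the error analysis.
    """
    df = trials
    if "practice" in df.columns:
        df = df.loc[~df["practice"]]
    out = (
        df.groupby(["subject_id", "treatment", "square_size"], sort=True, observed=True)
        .agg(
            responded=("censored", lambda c: int((~c).sum())),
            errors=("error", lambda e: int((e == True).sum())),  # noqa: E712
        )
        .reset_index()
    )
    return out


def _formula_rhs(fixed_terms: tuple[str, ...], reference: str = REFERENCE_TREATMENT) -> str:
    for t in fixed_terms:
        if t not in _ALLOWED_TERMS:
            raise ValueError(f"unknown fixed term {t!r}")
    if "size:treatment" in fixed_terms and not {"size", "treatment"} <= set(fixed_terms):
        raise ValueError("interaction requires both main effects")
    size_t = "C(square_size, Treatment('small'))"
    treat_t = f"C(treatment, Treatment('{reference}'))"
    parts = ["1"]
    if "size" in fixed_terms:
        parts.append(size_t)
    if "treatment" in fixed_terms:
        parts.append(treat_t)
    if "size:treatment" in fixed_terms:
        parts.append(f"{size_t}:{treat_t}")
    return " + ".join(parts)


def _design(data: pd.DataFrame, fixed_terms: tuple[str, ...]):
    levels = _levels(data, "treatment")
    ref = REFERENCE_TREATMENT if REFERENCE_TREATMENT in levels else levels[0]
    mat = patsy.dmatrix(_formula_rhs(fixed_terms, reference=ref), data, return_type="dataframe")
    return mat


def _binomial_marginal_loglik(
    beta: np.ndarray,
    tau: float,
    X_by_subj: list[np.ndarray],
    y_by_subj: list[np.ndarray],
    n_by_subj: list[np.ndarray],
    gh_x: np.ndarray,
    gh_w: np.ndarray,
) -> float:
    """Marginal log-likelihood via Laplace-centred Gauss-Hermite quadrature."""
    total = 0.0
    log_gh_w = np.log(gh_w)
    for X, y, n in zip(X_by_subj, y_by_subj, n_by_subj):
        eta0 = X @ beta
        if tau < 1e-8:
            total += float(np.sum(y * log_expit(eta0) + (n - y) * log_expit(-eta0)))
            continue
        # Newton iterations for the conditional mode of u
        u = 0.0
        h = -1.0 / tau**2
        for _ in range(60):
            p = expit(eta0 + u)
            g = float(np.sum(y - n * p)) - u / tau**2
            h = -float(np.sum(n * p * (1 - p))) - 1.0 / tau**2
            step = g / h
            u -= step
            if abs(step) < 1e-11:
                break
        sd = 1.0 / math.sqrt(-h)
        nodes = u + math.sqrt(2.0) * sd * gh_x
        eta = eta0[:, None] + nodes[None, :]
        f = (
            np.sum(y[:, None] * log_expit(eta) + (n - y)[:, None] * log_expit(-eta), axis=0)
            + norm.logpdf(nodes, 0.0, tau)
        )
        a = f + gh_x**2 + log_gh_w
        amax = np.max(a)
        total += amax + math.log(np.sum(np.exp(a - amax))) + math.log(math.sqrt(2.0) * sd)
    return total


def _fit_binomial(
    data: pd.DataFrame,
    fixed_terms: tuple[str, ...],
    quad_order: int = 15,
) -> ModelFit:
    mat = _design(data, fixed_terms)
    X = np.asarray(mat, float)
    y = data["errors"].to_numpy(float)
    n = data["responded"].to_numpy(float)
    if np.any(y > n):
        raise ValueError("errors cannot exceed responded")
    groups = data["subject_id"].to_numpy()
    notes: list[str] = []

    # treatment levels whose error counts are all 0 (or all 1) carry no
    # information on the logit scale: contrasts involving them are flagged
    non_est = set()
    if "treatment" in data.columns:
        for lev, g in data.groupby("treatment", observed=True):
            if g["errors"].sum() == 0 or (g["errors"] == g["responded"]).all():
                non_est.add(str(lev))
    if non_est:
        notes.append(f"zero-variance treatment levels: {sorted(non_est)}")

    const = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
    uniq = pd.unique(groups)
    idx = [np.flatnonzero(groups == g) for g in uniq]
    Xs = [X[i] for i in idx]
    ys = [y[i] for i in idx]
    ns = [n[i] for i in idx]
    gh_x, gh_w = np.polynomial.hermite.hermgauss(quad_order)

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(
            np.column_stack([y, n - y]), X, family=sm.families.Binomial()
        ).fit(maxiter=200)
    beta0 = np.clip(np.asarray(glm.params, float), -25, 25)

    if len(uniq) < 2:
        notes.append("single subject: intercept variance fixed at 0 (plain logistic fit)")
        warnings.warn("single subject: fitting a plain logistic model", stacklevel=2)
        ll = _binomial_marginal_loglik(beta0, 0.0, Xs, ys, ns, gh_x, gh_w) + const
        cov = pd.DataFrame(glm.cov_params(), index=mat.columns, columns=mat.columns)
        return ModelFit(
            "binomial_errors",
            tuple(fixed_terms),
            pd.Series(beta0, index=mat.columns),
            cov,
            0.0,
            ll,
            len(data),
            mat.design_info,
            _levels(data, "treatment"),
            _levels(data, "square_size"),
            frozenset(non_est),
            tuple(notes),
        )

    def negll(theta):
        beta, tau = theta[:-1], abs(theta[-1])
        return -_binomial_marginal_loglik(beta, tau, Xs, ys, ns, gh_x, gh_w)

    theta0 = np.append(beta0, 0.5)
    res = minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=[(-30, 30)] * len(beta0) + [(0.0, 20.0)],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    theta = res.x
    beta_hat, tau_hat = theta[:-1], abs(theta[-1])
    ll = -res.fun + const

    # covariance of the fixed effects from the observed information
    try:
        H = numdiff.approx_hess1(theta, negll)
        cov_full = np.linalg.inv(H)
        cov_beta = cov_full[: len(beta_hat), : len(beta_hat)]
        if np.any(np.diag(cov_beta) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        H = numdiff.approx_hess1(beta_hat, lambda b: negll(np.append(b, tau_hat)))
        cov_beta = np.linalg.pinv(H)
        notes.append("covariance from beta-only information (tau at boundary)")
    cov = pd.DataFrame(cov_beta, index=mat.columns, columns=mat.columns)
    return ModelFit(
        "binomial_errors",
        tuple(fixed_terms),
        pd.Series(beta_hat, index=mat.columns),
        cov,
        float(tau_hat**2),
        float(ll),
        len(data),
        mat.design_info,
        _levels(data, "treatment"),
        _levels(data, "square_size"),
        frozenset(non_est),
        tuple(notes),
    )


def _levels(data: pd.DataFrame, col: str) -> tuple[str, ...]:
    if col not in data.columns:
        return ()
    present = set(map(str, data[col].unique()))
    canon = TREATMENTS if col == "treatment" else ("small", "large")
    ordered = [l for l in canon if l in present]
    return tuple(ordered) or tuple(sorted(present))


def _fit_normal(data: pd.DataFrame, fixed_terms: tuple[str, ...], response: str) -> ModelFit:
    mat = _design(data, fixed_terms)
    endog = data[response].to_numpy(float)
    groups = data["subject_id"].to_numpy()
    notes: list[str] = []
    if len(pd.unique(groups)) < 2:
        import statsmodels.api as sm

        notes.append("single subject: fixed-effects (OLS) fit, intercept variance 0")
        warnings.warn("single subject: fitting a fixed-effects model", stacklevel=2)
        ols = sm.OLS(endog, np.asarray(mat)).fit()
        # ML (not OLS) residual variance so deviances stay comparable
        resid = endog - ols.fittedvalues
        s2 = float(np.mean(resid**2))
        ll = float(-0.5 * len(endog) * (math.log(2 * math.pi * s2) + 1))
        cov = pd.DataFrame(
            s2 * np.linalg.inv(np.asarray(mat).T @ np.asarray(mat)),
            index=mat.columns,
            columns=mat.columns,
        )
        return ModelFit(
            "normal_mean_rt",
            tuple(fixed_terms),
            pd.Series(np.asarray(ols.params), index=mat.columns),
            cov,
            0.0,
            ll,
            len(data),
            mat.design_info,
            _levels(data, "treatment"),
            _levels(data, "square_size"),
            notes=tuple(notes),
        )
    model = MixedLM(endog, np.asarray(mat), groups=groups)
    fit = None
    last_exc: Exception | None = None
    for method in ("bfgs", "lbfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=False, method=method, maxiter=500)
            break
        except np.linalg.LinAlgError as exc:  # singular information at optimum
            last_exc = exc
    if fit is None:
        raise RuntimeError("mixed-model fit failed with every optimiser") from last_exc
    k = mat.shape[1]
    cov = pd.DataFrame(
        np.asarray(fit.cov_params())[:k, :k], index=mat.columns, columns=mat.columns
    )
    return ModelFit(
        "normal_mean_rt",
        tuple(fixed_terms),
        pd.Series(np.asarray(fit.fe_params), index=mat.columns),
        cov,
        float(np.asarray(fit.cov_re)[0, 0]),
        float(fit.llf),
        len(data),
        mat.design_info,
        _levels(data, "treatment"),
        _levels(data, "square_size"),
        notes=tuple(notes),
    )


def fit_mixed(
    data: pd.DataFrame,
    response_kind: str,
    fixed_terms: tuple[str, ...] = ("size", "treatment", "size:treatment"),
    response: str = "mean_hat",
) -> ModelFit:
    """Fit a one-random-intercept model by maximum likelihood.

    ``normal_mean_rt`` expects one row per subject x treatment x size cell
    with the censoring-corrected mean in ``response``; ``binomial_errors``
    expects per-cell ``errors`` and ``responded`` counts (the likelihood is
    identical to Bernoulli trial rows, at a fraction of the cost).
    """
    fixed_terms = tuple(fixed_terms)
    for col in ("subject_id", "treatment", "square_size"):
        if col not in data.columns:
            raise ValueError(f"data must contain {col!r}")
    if response_kind == "normal_mean_rt":
        if "converged" in data.columns and not data["converged"].all():
            n_bad = int((~data["converged"]).sum())
            warnings.warn(f"dropping {n_bad} non-estimable cells", stacklevel=2)
            data = data.loc[data["converged"]]
        return _fit_normal(data, fixed_terms, response)
    if response_kind == "binomial_errors":
        return _fit_binomial(data, fixed_terms)
    raise ValueError(f"unknown response_kind {response_kind!r}")


def lrt(full: ModelFit, reduced: ModelFit, term: str = "") -> LrtResult:
    """Likelihood-ratio deviance test of nested ML fits."""
    if full.response_kind != reduced.response_kind:
        raise ValueError("fits must share a response kind")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits must use the same data")
    if not set(reduced.fixed_terms) <= set(full.fixed_terms):
        raise ValueError("reduced model is not nested in full model")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    stat = max(reduced.deviance - full.deviance, 0.0)
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    if not term:
        term = "+".join(sorted(set(full.fixed_terms) - set(reduced.fixed_terms))) or "none"
    return LrtResult(term=term, chi2=float(stat), df=df, p=p)


def _cell_rows(fit: ModelFit) -> dict[tuple[str, str], np.ndarray]:
    if fit._cell_row_cache is not None:
        return fit._cell_row_cache
    sizes = fit.size_levels or ("small",)
    treatments = fit.treatment_levels
    new = pd.DataFrame(
        [(t, s) for t in treatments for s in sizes], columns=["treatment", "square_size"]
    )
    (mat,) = patsy.build_design_matrices([fit.design_info], new)
    rows = np.asarray(mat)
    cache = {
        (t, s): rows[i]
        for i, (t, s) in enumerate((t, s) for t in treatments for s in sizes)
    }
    fit._cell_row_cache = cache
    return cache


def _treatment_contrast(fit: ModelFit, a: str, b: str) -> np.ndarray:
    """Contrast vector for treatment a minus b, averaged over size levels."""
    rows = _cell_rows(fit)
    sizes = fit.size_levels or ("small",)
    L = np.zeros(fit.n_fixed_params)
    for s in sizes:
        L += (rows[(a, s)] - rows[(b, s)]) / len(sizes)
    return L


def level_means(fit: ModelFit) -> dict[str, float]:
    """Model-predicted marginal mean per treatment (averaged over sizes)."""
    rows = _cell_rows(fit)
    sizes = fit.size_levels or ("small",)
    beta = fit.params.to_numpy()
    return {
        t: float(np.mean([rows[(t, s)] @ beta for s in sizes]))
        for t in fit.treatment_levels
    }


def contrasts_vs_reference(fit: ModelFit, reference: str = REFERENCE_TREATMENT) -> pd.DataFrame:
    """A-priori simple contrasts of every treatment against the reference.

    Tested simultaneously and deliberately without multiplicity
    correction.
    """
    if "treatment" not in fit.fixed_terms:
        raise ValueError("fit has no treatment term")
    if reference not in fit.treatment_levels:
        raise ValueError(f"reference level {reference!r} absent from fit")
    beta = fit.params.to_numpy()
    C = fit.cov.to_numpy()
    rows = []
    for t in fit.treatment_levels:
        if t == reference:
            continue
        L = _treatment_contrast(fit, t, reference)
        est = float(L @ beta)
        var = float(L @ C @ L)
        estimable = not ({t, reference} & fit.non_estimable_levels) and var > 0
        se = math.sqrt(var) if var > 0 else math.nan
        z = est / se if estimable else math.nan
        p = float(2 * norm.sf(abs(z))) if estimable else math.nan
        rows.append(
            {
                "pair": f"{t} - {reference}",
                "estimate": est,
                "se": se,
                "t": z,
                "p_raw": p,
                "p_adjusted": p,
                "adjustment": "none_simple_vs_reference",
                "estimable": estimable,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["level_means"] = level_means(fit)
    out.attrs["alpha_family"] = "simple_vs_reference"
    return out


def tukey_pairwise(
    fit: ModelFit,
    n_draws: int = TUKEY_MC_DRAWS,
    mc_seed: int = TUKEY_MC_SEED,
) -> pd.DataFrame:
    """All pairwise treatment comparisons with single-step adjustment.

    Adjusted p-values are P(max_j |Z_j| >= |z_i|) under the joint normal
    distribution of the estimable contrast statistics with their fitted
    correlation, evaluated by fixed-seed Monte Carlo integration.
    """
    if "treatment" not in fit.fixed_terms:
        raise ValueError("fit has no treatment term")
    beta = fit.params.to_numpy()
    C = fit.cov.to_numpy()
    pairs = list(itertools.combinations(fit.treatment_levels, 2))
    Ls, meta = [], []
    for a, b in pairs:
        L = _treatment_contrast(fit, a, b)
        estimable = not ({a, b} & fit.non_estimable_levels)
        Ls.append(L)
        meta.append([f"{a} - {b}", estimable])
    Lmat = np.vstack(Ls)
    est = Lmat @ beta
    V = Lmat @ C @ Lmat.T
    for i in range(len(pairs)):  # degenerate variance also blocks a pair
        if V[i, i] <= 0:
            meta[i][1] = False
    se = np.sqrt(np.clip(np.diag(V), 1e-300, None))
    z = est / se
    p_raw = 2 * norm.sf(np.abs(z))

    est_idx = [i for i, (_, ok) in enumerate(meta) if ok]
    p_adj = np.full(len(pairs), np.nan)
    if len(est_idx) == 1:
        p_adj[est_idx[0]] = p_raw[est_idx[0]]
    elif est_idx:
        R = V[np.ix_(est_idx, est_idx)] / np.outer(se[est_idx], se[est_idx])
        # symmetrise and regularise for the Cholesky draw
        R = (R + R.T) / 2 + 1e-10 * np.eye(len(est_idx))
        rng = np.random.default_rng(mc_seed)
        draws = rng.multivariate_normal(
            np.zeros(len(est_idx)), R, size=n_draws, method="cholesky"
        )
        maxabs = np.max(np.abs(draws), axis=1)
        for i in est_idx:
            p_adj[i] = float(np.mean(maxabs >= abs(z[i])))
        # the single-step adjusted p can never undercut the raw p
        p_adj[est_idx] = np.maximum(p_adj[est_idx], p_raw[est_idx])
    out = pd.DataFrame(
        {
            "pair": [m[0] for m in meta],
            "estimate": est,
            "se": se,
            "t": z,
            "p_raw": np.where([m[1] for m in meta], p_raw, np.nan),
            "p_adjusted": p_adj,
            "adjustment": "tukey_single_step",
            "estimable": [m[1] for m in meta],
        }
    )
    out.attrs["level_means"] = level_means(fit)
    out.attrs["mc_seed"] = mc_seed
    out.attrs["n_draws"] = n_draws
    return out


def ordering_summary(
    contrast_table: pd.DataFrame,
    alpha: float = 0.05,
    means: dict[str, float] | None = None,
) -> OrderingSummary:
    """Collapse a full pairwise table into an ordering string.

    Treatments are sorted by estimated marginal mean (descending) and
    grouped into maximal runs whose internal pairs are all non-significant
    at ``alpha``; non-estimable pairs cannot support a difference and are
    treated as non-significant.  Disjoint runs render as
    ``Border>(Square = Stripe)>(Dark = Light)``; a non-transitive pattern
    yields overlapping runs, rendered with ``>=`` between them plus a
    warning.
    """
    if means is None:
        means = contrast_table.attrs.get("level_means")
    if means is None:
        raise ValueError("no level means available for ordering")
    levels = sorted(means, key=lambda l: -means[l])
    sig: dict[frozenset, bool] = {}
    for _, row in contrast_table.iterrows():
        a, b = [s.strip() for s in row["pair"].split(" - ")]
        is_sig = bool(row["estimable"]) and float(row["p_adjusted"]) < alpha
        sig[frozenset((a, b))] = is_sig
    for a, b in itertools.combinations(levels, 2):
        if frozenset((a, b)) not in sig:
            raise ValueError(f"pair {a} vs {b} missing from contrast table")

    runs: list[tuple[int, int]] = []
    for i in range(len(levels)):
        j = i
        while j + 1 < len(levels) and not any(
            sig[frozenset((levels[k], levels[j + 1]))] for k in range(i, j + 1)
        ):
            j += 1
        if not runs or j > runs[-1][1]:
            runs.append((i, j))
    groups = tuple(tuple(sorted(levels[i : j + 1])) for i, j in runs)
    overlapping = any(runs[k][1] >= runs[k + 1][0] for k in range(len(runs) - 1))

    def render(g: tuple[str, ...]) -> str:
        return g[0] if len(g) == 1 else "(" + " = ".join(g) + ")"

    parts = [render(groups[0])]
    for k in range(1, len(groups)):
        sep = ">=" if runs[k - 1][1] >= runs[k][0] else ">"
        parts.append(sep + render(groups[k]))
    text = "".join(parts)
    if overlapping:
        warnings.warn(
            "non-transitive significance pattern; ordering groups overlap", stacklevel=2
        )
    return OrderingSummary(groups=groups, text=text, overlapping=overlapping, alpha=alpha)


def anova_crosscheck(cells: pd.DataFrame) -> pd.DataFrame:
    """Classical repeated-measures ANOVA cross-check.

    F-tests for size, treatment and their interaction on the cell mean RTs
    and on arc-sine-square-root transformed error proportions, with subject
    as the (random) blocking factor.  Requires a balanced table: exactly
    one row per subject x treatment x size cell.
    """
    from statsmodels.stats.anova import AnovaRM

    if cells["subject_id"].nunique() < 2:
        raise ValueError("anova_crosscheck needs at least two subjects")
    counts = cells.groupby(["subject_id", "treatment", "square_size"], observed=True).size()
    if (counts != 1).any() or len(counts) != cells["subject_id"].nunique() * cells[
        "treatment"
    ].nunique() * cells["square_size"].nunique():
        raise ValueError("anova_crosscheck requires one row per subject x treatment x size")
    work = cells.copy()
    responses = [("mean_rt", "mean_hat")]
    if "err_prop" in work.columns:
        p = work["err_prop"].to_numpy(float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("err_prop must lie in [0, 1]")
        work["asin_sqrt_err"] = np.arcsin(np.sqrt(p))
        responses.append(("errors_asin_sqrt", "asin_sqrt_err"))
    rows = []
    for label, col in responses:
        res = AnovaRM(
            work, depvar=col, subject="subject_id", within=["square_size", "treatment"]
        ).fit()
        tbl = res.anova_table
        name_map = {
            "square_size": "size",
            "treatment": "treatment",
            "square_size:treatment": "size:treatment",
        }
        for term, r in tbl.iterrows():
            rows.append(
                {
                    "response": label,
                    "term": name_map.get(term, term),
                    "F": float(r["F Value"]),
                    "df_num": float(r["Num DF"]),
                    "df_den": float(r["Den DF"]),
                    "p": float(r["Pr > F"]),
                }
            )
    return pd.DataFrame(rows)


def arcsine_sqrt(p):
    """Variance-stabilising transform for proportions: arcsin(sqrt(p))."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def _lrt_to_dict(r: LrtResult) -> dict:
    return {"term": r.term, "chi2": r.chi2, "df": r.df, "p": r.p}


def _analyse_kind(data: pd.DataFrame, kind: str, alpha: float) -> dict:
    """Decision tree for one response: interaction first, then mains.

    A significant size-by-treatment interaction sends the analysis down the
    per-size branch (treatment tested and ordered within each square size);
    otherwise treatment comparisons come from the additive model.
    """
    multi_size = data["square_size"].nunique() > 1
    if not multi_size:
        fit_t = fit_mixed(data, kind, ("treatment",))
        fit_0 = fit_mixed(data, kind, ())
        simple = contrasts_vs_reference(fit_t)
        tukey = tukey_pairwise(fit_t)
        return {
            "lrt": {"treatment": _lrt_to_dict(lrt(fit_t, fit_0, "treatment"))},
            "contrasts_vs_reference": simple,
            "tukey": tukey,
            "ordering": ordering_summary(tukey, alpha),
            "branch": "single_size",
        }
    full = fit_mixed(data, kind, ("size", "treatment", "size:treatment"))
    additive = fit_mixed(data, kind, ("size", "treatment"))
    size_only = fit_mixed(data, kind, ("size",))
    treat_only = fit_mixed(data, kind, ("treatment",))
    res: dict = {
        "lrt": {
            "size:treatment": _lrt_to_dict(lrt(full, additive, "size:treatment")),
            "treatment": _lrt_to_dict(lrt(additive, size_only, "treatment")),
            "size": _lrt_to_dict(lrt(additive, treat_only, "size")),
        },
        "subject_intercept_variance": full.subject_intercept_variance,
        "non_estimable_levels": sorted(full.non_estimable_levels),
    }
    if res["lrt"]["size:treatment"]["p"] < alpha:
        res["branch"] = "per_size"
        res["per_size"] = {}
        for size, sub in data.groupby("square_size", observed=True):
            res["per_size"][str(size)] = _analyse_kind(sub.copy(), kind, alpha)
    else:
        res["branch"] = "pooled"
        simple = contrasts_vs_reference(additive)
        tukey = tukey_pairwise(additive)
        res["contrasts_vs_reference"] = simple
        res["tukey"] = tukey
        res["ordering"] = ordering_summary(tukey, alpha)
    return res


def analyse_experiment(
    cells: pd.DataFrame, errors: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Run the full inferential chain on estimated cells and error counts.

    Returns a nested report: deviance tests for interaction and main
    effects, reference contrasts, Tukey-adjusted pairwise comparisons and
    an ordering summary for each response (with per-size sub-analyses
    whenever the interaction is significant), plus the classical ANOVA
    cross-check when the design is balanced.
    """
    report = {
        "alpha": alpha,
        "rt": _analyse_kind(cells, "normal_mean_rt", alpha),
        "errors": _analyse_kind(errors, "binomial_errors", alpha),
    }
    merged = cells.merge(errors, on=["subject_id", "treatment", "square_size"], how="inner")
    merged["err_prop"] = np.where(
        merged["responded"] > 0, merged["errors"] / merged["responded"], np.nan
    )
    try:
        report["anova_crosscheck"] = anova_crosscheck(
            merged.dropna(subset=["err_prop", "mean_hat"])
        )
    except ValueError as exc:
        report["anova_crosscheck"] = None
        report["anova_crosscheck_skipped"] = str(exc)
    return report
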