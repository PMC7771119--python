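"""AICc-ranked linear mixed models for herbivore assemblage responses.

Responses (one row per plant species x guild, transformed as declared by
the interactions module) are modeled against up to four fixed factors —
phylogenetic isolation (PI), square-root leaf area, sampling site and
feeding guild — plus the guild x site interaction, with host tree species
identity as a random intercept (exposed and shelter rows of the same tree
are not independent).

The candidate set is every additive subset of the four factors (including
the intercept-only null model) plus, for each subset containing both guild
and site, a variant adding the interaction: 16 + 4 = 20 specifications.
Fits are maximum likelihood (not REML: AICc comparisons span different
fixed structures). Models are ranked by AICc with Akaike weights; the
selected model is the one with fewest parameters among those within 2 AICc
units of the minimum, and is tested against the null by a chi-square
likelihood-ratio test. Guild contrasts per site use Holm-adjusted Wald
tests (a multiplicity-adjusted stand-in for Tukey's HSD, which is not
defined without extra multivariate-t machinery; flagged in the output).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

#: Candidate fixed factors, in canonical order.
FACTORS = ("pi", "leaf_area_sqrt", "site", "guild")

RESPONSES = ("abundance", "density", "richness", "mean_dsi_star")


@dataclass(frozen=True, order=True)
class ModelSpec:
    """One candidate fixed-effect structure (random intercept is implicit)."""

    response: str
    fixed: tuple[str, ...] = ()
    interaction: bool = False

    def __post_init__(self):
        unknown = set(self.fixed) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")
        object.__setattr__(
            self, "fixed", tuple(f for f in FACTORS if f in self.fixed)
        )
        if self.interaction and not {"guild", "site"} <= set(self.fixed):
            raise ValueError("guild x site interaction requires both main effects")

    @property
    def is_null(self) -> bool:
        return not self.fixed

    def formula(self, response_col: str = "value") -> str:
        terms = []
        for f in self.fixed:
            terms.append(f"C({f})" if f in ("site", "guild") else f)
        if self.interaction:
            terms.append("C(guild):C(site)")
        rhs = " + ".join(terms) if terms else "1"
        return f"{response_col} ~ {rhs}"

    def label(self) -> str:
        if self.is_null:
            return "null"
        out = " + ".join(self.fixed)
        if self.interaction:
            out += " + guild:site"
        return out


def candidate_set(response: str) -> list[ModelSpec]:
    """All additive subsets of the four factors, plus guild x site variants."""
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    specs = []
    for r in range(len(FACTORS) + 1):
        for subset in itertools.combinations(FACTORS, r):
            specs.append(ModelSpec(response, subset))
            if {"guild", "site"} <= set(subset):
                specs.append(ModelSpec(response, subset, interaction=True))
    return specs


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate mixed model."""

    spec: ModelSpec
    n_obs: int
    k: int
    loglik: float
    aicc: float
    coefficients: pd.Series
    bse: pd.Series
    converged: bool
    delta_aicc: float | None = None
    weight: float | None = None
    result: object = field(default=None, repr=False)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1); undefined for n <= k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_full_rank(formula: str, table: pd.DataFrame) -> None:
    X = patsy.dmatrix(formula.split("~", 1)[1], table, return_type="matrix")
    X = np.asarray(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = X.design_info.column_names if hasattr(X, "design_info") else []
        raise ValueError(f"rank-deficient design for formula {formula!r} {names}")


def fit_lmm(
    spec: ModelSpec, table: pd.DataFrame, response_col: str = "value"
) -> FitResult:
    """Fit one candidate LMM by maximum likelihood.

    ``table`` needs columns ``tree_id`` (random-intercept grouping: the host
    tree species), the factors referenced by the spec, and the (already
    transformed) response in ``response_col``. ``k`` counts the fixed
    coefficients (incl. intercept) plus the random-intercept variance and
    the residual variance.
    """
    required = {"tree_id", response_col} | set(spec.fixed)
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    data = table.dropna(subset=[response_col]).copy()
    formula = spec.formula(response_col)
    _check_full_rank(formula, data)
    model = sm.MixedLM.from_formula(formula, groups=data["tree_id"], data=data)
    # variance components near zero stall some optimizers; walk through a
    # ladder of methods until one converges
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.debug("fit %s failed with %s: %s", spec.label(), method, exc)
                continue
            if res is None or (cand.converged and not res.converged):
                res = cand
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
        if res is None:
            logger.warning("all optimizers failed for %s", spec.label())
            return FitResult(spec, len(data), 0, np.nan, np.nan,
                             pd.Series(dtype=float), pd.Series(dtype=float), False)
        coefficients = res.fe_params.copy()
        bse = res.bse_fe.copy()
    k = len(res.fe_params) + 2
    n = len(data)
    if n < k + 2:
        raise ValueError(f"too few rows ({n}) to fit {spec.label()} with k={k}")
    converged = bool(res.converged) and np.isfinite(res.llf)
    return FitResult(
        spec=spec,
        n_obs=n,
        k=k,
        loglik=float(res.llf),
        aicc=aicc(float(res.llf), k, n) if converged else np.nan,
        coefficients=coefficients,
        bse=bse,
        converged=converged,
        result=res,
    )


def rank_and_select(fits: Sequence[FitResult]) -> tuple[pd.DataFrame, FitResult]:
    """Rank converged fits by AICc; select the best model.

    Akaike weight w_m = exp(-delta_m / 2) normalized over the set. The best
    model is the one with the smallest k among all fits with delta AICc <= 2
    (parsimony rule); ties on k break by smaller AICc, then by spec order.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    dropped = len(fits) - len(usable)
    if dropped:
        logger.warning("excluding %d non-converged fits from ranking", dropped)
    if len(usable) < 1:
        raise ValueError("no converged fits to rank")
    best_aicc = min(f.aicc for f in usable)
    rel = np.array([np.exp(-(f.aicc - best_aicc) / 2.0) for f in usable])
    weights = rel / rel.sum()
    for f, w in zip(usable, weights):
        f.delta_aicc = f.aicc - best_aicc
        f.weight = float(w)
    candidates = [f for f in usable if f.delta_aicc <= 2.0]
    best = min(candidates, key=lambda f: (f.k, f.aicc, f.spec))
    table = pd.DataFrame(
        {
            "model": [f.spec.label() for f in usable],
            "k": [f.k for f in usable],
            "n_obs": [f.n_obs for f in usable],
            "loglik": [f.loglik for f in usable],
            "aicc": [f.aicc for f in usable],
            "delta_aicc": [f.delta_aicc for f in usable],
            "weight": [f.weight for f in usable],
            "selected": [f is best for f in usable],
        }
    ).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    return table, best


def lrt_vs_null(best_fit: FitResult, null_fit: FitResult) -> dict:
    """Chi-square likelihood-ratio test of the selected model vs the null."""
    if not null_fit.spec.is_null:
        raise ValueError("null_fit must be the intercept-only model")
    if not set(null_fit.spec.fixed) <= set(best_fit.spec.fixed):
        raise ValueError("models are not nested")
    if best_fit.n_obs != null_fit.n_obs:
        raise ValueError("fits use different rows; LRT invalid")
    chi2 = 2.0 * (best_fit.loglik - null_fit.loglik)
    if chi2 < -1e-8:
        raise ValueError(
            "selected model has lower ML log-likelihood than the null; fit failure"
        )
    chi2 = max(chi2, 0.0)
    df = best_fit.k - null_fit.k
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": float(chi2), "df": int(df), "p": p}


def guild_site_contrasts(best_fit: FitResult, table: pd.DataFrame) -> pd.DataFrame:
    """Exposed-vs-shelter Wald contrasts of the fixed effects at each site.

    Holm-adjusted across sites. Returns an empty frame (not an error) when
    the selected model lacks guild or site. The adjustment is a documented
    stand-in for a Tukey HSD.
    """
    spec = best_fit.spec
    if "guild" not in spec.fixed or "site" not in spec.fixed:
        logger.info("selected model lacks guild and/or site; contrasts not applicable")
        return pd.DataFrame(
            columns=["site", "estimate", "se", "z", "p", "p_holm", "adjustment"]
        )
    res = best_fit.result
    design_info = res.model.data.design_info
    sites = sorted(table["site"].unique())
    cov = np.asarray(res.cov_params())[: len(res.fe_params), : len(res.fe_params)]
    params = np.asarray(res.fe_params)
    rows = []
    for site in sites:
        base = {"pi": 0.0, "leaf_area_sqrt": 0.0, "site": site}
        x_exp = np.asarray(
            patsy.dmatrix(design_info, pd.DataFrame([{**base, "guild": "exposed"}]))
        )[0]
        x_she = np.asarray(
            patsy.dmatrix(design_info, pd.DataFrame([{**base, "guild": "shelter"}]))
        )[0]
        L = x_exp - x_she
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se
        rows.append({"site": site, "estimate": est, "se": se, "z": z,
                     "p": float(2 * stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    out["adjustment"] = "holm_wald"
    return out


def fit_candidates(
    response: str, table: pd.DataFrame, response_col: str = "value"
) -> list[FitResult]:
    """Fit the full candidate set for one response."""
    return [fit_lmm(spec, table, response_col) for spec in candidate_set(response)]


def check_pi_leafarea_confounding(community: pd.DataFrame) -> dict:
    """OLS pre-check: does leaf area depend on phylogenetic isolation?

    Regresses square-root leaf area on PI with site as a covariate (dropped,
    with a warning, when fewer than two sites are present). A clear
    relationship here colors the interpretation of PI effects downstream.
    """
    for col in ("pi", "leaf_area_m2", "site"):
        if col not in community.columns:
            raise ValueError(f"community table missing column {col!r}")
    data = community.assign(leaf_area_sqrt=np.sqrt(community["leaf_area_m2"]))
    n_sites = data["site"].nunique()
    if n_sites < 2:
        logger.warning("fewer than 2 sites; dropping site covariate from pre-check")
        formula = "leaf_area_sqrt ~ pi"
    else:
        formula = "leaf_area_sqrt ~ pi + C(site)"
    res = smf.ols(formula, data=data).fit()
    return {
        "slope": float(res.params["pi"]),
        "slope_se": float(res.bse["pi"]),
        "slope_ci": tuple(np.asarray(res.conf_int().loc["pi"], dtype=float)),
        "r2_adj": float(res.rsquared_adj),
        "F": float(res.fvalue),
        "df": (int(res.df_model), int(res.df_resid)),
        "p": float(res.f_pvalue),
        "n": int(res.nobs),
    }
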