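"""Mixed-effects models linking controllability to degree and gray matter.

Two model families are supported, both with a participant random intercept
and fixed slopes:

* model 1: ``response ~ tiv + regions + degree × rgm + (1|participants)``
* model 2: ``response ~ tiv + regions × degree + regions × rgm + (1|participants)``

Formulas are parsed from a restricted grammar; region factors use treatment
contrasts against the alphabetically first region. Likelihood-ratio stepwise
selection requires ML fits; Wald 95% intervals and asymptotic (z) p-values
are reported, with Bonferroni correction over each term family.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .table import StudyTable

__all__ = [
    "ModelSpec",
    "ModelResult",
    "CoefficientEstimate",
    "parse_formula",
    "model1_spec",
    "model2_spec",
    "fit_lme",
    "stepwise_select",
    "regional_effects",
]

logger = logging.getLogger(__name__)

_Z975 = scipy.stats.norm.ppf(0.975)

#: canonical scalar variables usable in fixed-effect terms
_VARIABLES = {"tiv": "tiv", "degree": "strength", "strength": "strength", "rgm": "rgm"}
_RANDOM_LITERALS = {"(1|participants)", "(1|participant)", "(1|subject)"}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effects structure of one mixed model (random intercept implied)."""

    response: str
    fixed_terms: tuple[str, ...]
    label: str = ""

    def with_term(self, term: str) -> "ModelSpec":
        if term in self.fixed_terms:
            return self
        return ModelSpec(
            response=self.response,
            fixed_terms=self.fixed_terms + (_canonical_term(term),),
            label=self.label,
        )

    def formula(self) -> str:
        return (
            f"{self.response} ~ "
            + " + ".join(self.fixed_terms)
            + " + (1|participants)"
        )


@dataclass(frozen=True)
class CoefficientEstimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bonf: float
    term: str


@dataclass
class ModelResult:
    """Fitted mixed model: coefficient table plus fit diagnostics."""

    spec: ModelSpec
    coefficients: dict[str, CoefficientEstimate]
    log_likelihood: float
    n_obs: int
    n_params: int
    converged: bool
    fit_method: str
    group_var: float
    resid_var: float
    reference_region: str
    term_groups: dict[str, list[str]] = field(default_factory=dict)
    _fe_params: pd.Series | None = field(default=None, repr=False)
    _cov_params: pd.DataFrame | None = field(default=None, repr=False)
    diagnostics: str = ""

    def coefficient_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": name,
                "term": c.term,
                "beta": c.beta,
                "se": c.se,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_raw": c.p_raw,
                "p_bonf": c.p_bonf,
            }
            for name, c in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def _canonical_term(term: str) -> str:
    parts = [p.strip() for p in term.split(":")]
    out = []
    for p in parts:
        key = p.lower()
        if key in ("regions", "region"):
            out.append("regions")
        elif key in _VARIABLES:
            out.append("degree" if key == "strength" else key)
        else:
            raise ValueError(f"unknown variable {p!r} in term {term!r}")
    if len(out) > 2:
        raise ValueError(f"only two-way interactions supported, got {term!r}")
    if len(out) == 2:
        # put the region factor first for a stable name
        if out[1] == "regions":
            out = [out[1], out[0]]
        return ":".join(out)
    return out[0]


def parse_formula(text: str) -> ModelSpec:
    """Parse ``response ~ term + term×term + (1|participants)``.

    ``×`` and ``*`` expand to both main effects plus the interaction; ``:``
    is the pure interaction. The random-intercept literal is accepted and
    implied if absent; any other random structure is rejected.
    """
    if "~" not in text:
        raise ValueError(f"formula {text!r} lacks '~'")
    lhs, rhs = text.split("~", 1)
    response = lhs.strip().lower()
    if response not in ("ac", "mc"):
        raise ValueError(f"response must be 'ac' or 'mc', got {response!r}")
    terms: list[str] = []
    for raw in rhs.split("+"):
        tok = raw.strip()
        if not tok:
            continue
        if tok.replace(" ", "") in _RANDOM_LITERALS:
            continue
        if tok.startswith("("):
            raise ValueError(f"unsupported random term {tok!r}")
        tok = tok.replace("×", "*")
        if "*" in tok:
            a, b = [t.strip() for t in re.split(r"\*", tok, maxsplit=1)]
            for t in (a, b, f"{a}:{b}"):
                c = _canonical_term(t)
                if c not in terms:
                    terms.append(c)
        else:
            c = _canonical_term(tok)
            if c not in terms:
                terms.append(c)
    if not terms:
        raise ValueError("no fixed-effect terms in formula")
    return ModelSpec(response=response, fixed_terms=tuple(terms))


def model1_spec(response: str = "ac") -> ModelSpec:
    """``response ~ tiv + regions + degree × rgm + (1|participants)``"""
    spec = parse_formula(f"{response} ~ tiv + regions + degree × rgm")
    return ModelSpec(spec.response, spec.fixed_terms, label="model1")


def model2_spec(response: str = "ac") -> ModelSpec:
    """``response ~ tiv + regions × degree + regions × rgm + (1|participants)``"""
    spec = parse_formula(f"{response} ~ tiv + regions × degree + regions × rgm")
    return ModelSpec(spec.response, spec.fixed_terms, label="model2")


def _build_design(
    scaled: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[pd.DataFrame, dict[str, list[str]], str]:
    """Expand canonical terms into a named design matrix with intercept."""
    regions = sorted(scaled["region_name"].unique())
    reference = regions[0]
    dummies = pd.get_dummies(
        pd.Categorical(scaled["region_name"], categories=regions),
        prefix="", prefix_sep="", dtype=float,
    ).iloc[:, 1:]  # drop reference level
    dummies.columns = [f"region[T.{r}]" for r in regions[1:]]
    dummies.index = scaled.index

    columns: dict[str, np.ndarray] = {"Intercept": np.ones(len(scaled))}
    groups: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    for term in terms:
        cols: list[str] = []
        if term == "regions":
            for c in dummies.columns:
                columns[c] = dummies[c].to_numpy()
                cols.append(c)
        elif ":" in term:
            a, b = term.split(":")
            if a == "regions":
                var = scaled[_VARIABLES[b]].to_numpy()
                for c in dummies.columns:
                    name = f"{c}:{b}"
                    columns[name] = dummies[c].to_numpy() * var
                    cols.append(name)
            else:
                name = f"{a}:{b}"
                columns[name] = (
                    scaled[_VARIABLES[a]].to_numpy() * scaled[_VARIABLES[b]].to_numpy()
                )
                cols.append(name)
        else:
            columns[term] = scaled[_VARIABLES[term]].to_numpy(dtype=float)
            cols.append(term)
        groups[term] = cols
    X = pd.DataFrame(columns, index=scaled.index)
    return X, groups, reference


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Column names made redundant by earlier columns (QR with pivoting)."""
    arr = X.to_numpy()
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = (diag.max() if diag.size else 0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    return sorted(X.columns[i] for i in piv[rank:])


class _RandomInterceptFit(NamedTuple):
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    llf: float
    converged: bool
    message: str


def _fit_random_intercept(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, reml: bool
) -> _RandomInterceptFit:
    """ML/REML fit of y = Xb + u_group + e by 1-D profiled likelihood.

    With V* = I + theta * Z Z' (theta = tau²/sigma²), beta and sigma² have
    closed GLS forms for fixed theta via per-group rank-one downdates, so
    only theta is optimized — which is robust at the theta = 0 boundary that
    within-subject-centered responses produce.
    """
    n, p = X.shape
    n_groups = int(codes.max()) + 1
    ng = np.bincount(codes, minlength=n_groups).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    S = np.zeros((n_groups, p))
    np.add.at(S, codes, X)
    t = np.bincount(codes, weights=y, minlength=n_groups)

    dof = n - p if reml else n

    def profile(theta: float):
        c = theta / (1.0 + theta * ng)
        A = XtX - (S.T * c) @ S
        b = Xty - S.T @ (c * t)
        try:
            cho = scipy.linalg.cho_factor(A)
            beta = scipy.linalg.cho_solve(cho, b)
        except scipy.linalg.LinAlgError:
            return np.inf, None
        rss = yty - float(np.sum(c * t * t)) - float(b @ beta)
        if rss <= 0:
            return np.inf, None
        sigma2 = rss / dof
        logdet_v = float(np.sum(np.log1p(theta * ng)))
        ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma2) + logdet_v + dof)
        if reml:
            logdet_a = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
            ll -= 0.5 * (logdet_a - p * np.log(sigma2))
        return -ll, (beta, sigma2, A)

    best_u = scipy.optimize.minimize_scalar(
        lambda u: profile(np.exp(u))[0],
        bounds=(-18.0, 18.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [(profile(0.0)[0], 0.0)]
    if np.isfinite(best_u.fun):
        candidates.append((best_u.fun, float(np.exp(best_u.x))))
    neg_ll, theta = min(candidates, key=lambda c: c[0])
    neg_ll, extras = profile(theta)
    if extras is None or not np.isfinite(neg_ll):
        return _RandomInterceptFit(
            beta=np.full(p, np.nan), cov_beta=np.full((p, p), np.nan),
            sigma2=np.nan, tau2=np.nan, llf=np.nan, converged=False,
            message="profiled likelihood not finite at optimum",
        )
    beta, sigma2, A = extras
    cov_beta = sigma2 * np.linalg.inv(A)
    message = "variance at boundary (tau2 = 0)" if theta == 0.0 else ""
    return _RandomInterceptFit(
        beta=beta, cov_beta=cov_beta, sigma2=sigma2, tau2=theta * sigma2,
        llf=-neg_ll, converged=True, message=message,
    )


def fit_lme(T: StudyTable, spec: ModelSpec, method: str = "ML") -> ModelResult:
    """Fit the linear mixed model with a participant random intercept.

    ``method`` is ``"ML"`` (required for likelihood-ratio comparisons) or
    ``"REML"``. Non-convergence is reported via ``converged=False`` rather
    than raised.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    if T.scaled is None:
        raise ValueError("StudyTable has no scaled view; call center_and_scale first")
    scaled = T.scaled
    if scaled["subject_id"].nunique() < 2:
        raise ValueError("mixed model requires at least 2 participants")
    X, groups, reference = _build_design(scaled, spec.fixed_terms)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"rank-deficient fixed-effects design; aliased terms: "
            f"{_aliased_columns(X)}"
        )
    y = scaled[spec.response].to_numpy(dtype=float)
    codes = pd.Categorical(scaled["subject_id"]).codes.astype(np.int64)
    fit = _fit_random_intercept(y, X.to_numpy(), codes, reml=(method == "REML"))
    if not fit.converged:
        logger.warning("LME fit did not converge: %s", fit.message)
        return ModelResult(
            spec=spec, coefficients={}, log_likelihood=np.nan,
            n_obs=len(y), n_params=X.shape[1], converged=False,
            fit_method=method, group_var=np.nan, resid_var=np.nan,
            reference_region=reference, term_groups=groups,
            diagnostics=fit.message,
        )
    converged = True
    diagnostics = fit.message

    fe = pd.Series(fit.beta, index=X.columns)
    k = X.shape[1]
    cov = pd.DataFrame(fit.cov_beta, index=X.columns, columns=X.columns)
    se = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    col_term = {c: t for t, cols in groups.items() for c in cols}
    coefficients: dict[str, CoefficientEstimate] = {}
    for name in X.columns:
        b, s = float(fe[name]), float(se[name])
        z = b / s if s > 0 else np.inf * np.sign(b)
        p = float(2 * scipy.stats.norm.sf(abs(z)))
        m = len(groups[col_term[name]])
        coefficients[name] = CoefficientEstimate(
            beta=b, se=s, ci_low=b - _Z975 * s, ci_high=b + _Z975 * s,
            p_raw=p, p_bonf=min(1.0, p * m), term=col_term[name],
        )
    return ModelResult(
        spec=spec,
        coefficients=coefficients,
        log_likelihood=float(fit.llf),
        n_obs=len(y),
        n_params=k,
        converged=converged,
        fit_method=method,
        group_var=float(fit.tau2),
        resid_var=float(fit.sigma2),
        reference_region=reference,
        term_groups=groups,
        _fe_params=fe,
        _cov_params=cov,
        diagnostics=diagnostics,
    )


def stepwise_select(
    T: StudyTable,
    base: ModelSpec,
    candidate_terms: list[str],
    alpha: float = 0.05,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Forward stepwise selection by ML likelihood-ratio tests.

    Candidates are tried in the given order; a term is retained iff the
    chi-square LR test (df = number of added design columns) has p < alpha.
    Returns the winning spec and the full trace.
    """
    if not candidate_terms:
        raise ValueError("candidate term list is empty")
    current = base
    current_fit = fit_lme(T, current, method="ML")
    trace_rows = []
    for term in candidate_terms:
        canon = _canonical_term(term)
        candidate = current.with_term(canon)
        if candidate.fixed_terms == current.fixed_terms:
            raise ValueError(f"candidate {term!r} already in model")
        cand_fit = fit_lme(T, candidate, method="ML")
        df_added = cand_fit.n_params - current_fit.n_params
        lr = 2.0 * (cand_fit.log_likelihood - current_fit.log_likelihood)
        if -1e-6 < lr < 0:
            lr = 0.0
        p = float(scipy.stats.chi2.sf(lr, df_added))
        kept = bool(p < alpha and cand_fit.converged)
        trace_rows.append(
            {"term": canon, "lr_stat": lr, "df": df_added, "p": p, "kept": kept}
        )
        if kept:
            current, current_fit = candidate, cand_fit
    return current, pd.DataFrame(trace_rows)


def regional_effects(result: ModelResult, family: str) -> pd.DataFrame:
    """Per-region slopes for a ``regions×rgm`` or ``regions×degree`` family.

    The reference region's slope is the main effect; every other region's is
    main effect plus its interaction delta, with standard errors from the
    coefficient covariance. Bonferroni correction uses the number of regions.
    """
    fam = _canonical_term(family.replace("×", ":").replace("*", ":"))
    if fam not in ("regions:rgm", "regions:degree"):
        raise ValueError(f"family must be regions×rgm or regions×degree, got {family!r}")
    main = fam.split(":")[1]
    if fam not in result.term_groups or main not in result.term_groups:
        raise ValueError(
            f"family {fam!r} absent from fitted model "
            f"(terms: {list(result.term_groups)})"
        )
    if result._fe_params is None or result._cov_params is None:
        raise ValueError("model result carries no parameter covariance")
    fe, cov = result._fe_params, result._cov_params
    b_main = float(fe[main])
    v_main = float(cov.loc[main, main])
    regions = [result.reference_region] + [
        c.split("[T.", 1)[1].split("]:", 1)[0] for c in result.term_groups[fam]
    ]
    m = len(regions)
    rows = []
    for region in regions:
        if region == result.reference_region:
            beta, var = b_main, v_main
        else:
            ic = f"region[T.{region}]:{main}"
            beta = b_main + float(fe[ic])
            var = v_main + float(cov.loc[ic, ic]) + 2.0 * float(cov.loc[main, ic])
        s = float(np.sqrt(var))
        p = float(2 * scipy.stats.norm.sf(abs(beta) / s)) if s > 0 else 0.0
        rows.append(
            {
                "region": region,
                "beta": beta,
                "se": s,
                "ci_low": beta - _Z975 * s,
                "ci_high": beta + _Z975 * s,
                "p_raw": p,
                "p_bonf": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)
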