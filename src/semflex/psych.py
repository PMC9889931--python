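"""Validation statistics for score matrices.

Implements the toolkit used to establish the reliability and construct
validity of divergent-thinking scores: rank and product-moment
correlations with Fisher-transform confidence intervals, the
independent-samples Fisher r-to-z comparison of two correlations,
internal-consistency reliabilities (Cronbach's alpha, McDonald's omega,
Hancock's coefficient H), and maximum-likelihood confirmatory factor
analysis with the standard chi-square-based and residual-based fit
indices (RMSEA with its noncentrality confidence interval, CFI, TLI,
SRMR).

The CFA minimizes the ML discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over free loadings, factor correlations, residual variances and the
residual covariances the model spec allows, with every factor variance
fixed to 1 for identification; chi-square = (n - 1) F_min.  Plain ML is
used throughout (no robust corrections).
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CorrelationResult",
    "CFAModelSpec",
    "CFAResult",
    "FitIndices",
    "ReliabilitySet",
    "spearman_rho",
    "pearson_r_ci",
    "fisher_z_compare",
    "steiger_z_compare",
    "cronbach_alpha",
    "composite_reliability",
    "fit_cfa",
    "independence_model",
    "fit_indices",
    "rmsea_from_chi2",
    "rmsea_confidence_interval",
    "load_cfa_spec",
]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    method: str


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def _fisher_ci(r: float, n: int, level: float) -> tuple[float, float]:
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return math.tanh(z - crit * se), math.tanh(z + crit * se)


def spearman_rho(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation with a Fisher r-to-z confidence interval.

    Ties receive average ranks.  Requires at least 4 complete pairs;
    constant input has no defined rank correlation.
    """
    xc, yc = _complete_pairs(x, y)
    n = len(xc)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(xc, yc)
    lo, hi = _fisher_ci(float(rho), n, ci_level) if abs(rho) < 1 else (rho, rho)
    return CorrelationResult(float(rho), n, float(p), lo, hi, "spearman")


def pearson_r_ci(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Pearson product-moment correlation with a Fisher r-to-z confidence interval.

    The point estimate needs 3 complete pairs; the Fisher interval needs
    n > 3 and is NaN below that.
    """
    xc, yc = _complete_pairs(x, y)
    n = len(xc)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(xc, yc)
    if n > 3 and abs(r) < 1:
        lo, hi = _fisher_ci(float(r), n, ci_level)
    elif abs(r) >= 1:
        lo, hi = float(r), float(r)
    else:
        lo = hi = float("nan")
    return CorrelationResult(float(r), n, float(p), lo, hi, "pearson")


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Independent-samples z test comparing two correlations.

    z = (atanh(r2) - atanh(r1)) / sqrt(1/(n1-3) + 1/(n2-3)); positive
    when r2 exceeds r1.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("Fisher transform is infinite at |r| = 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    return (math.atanh(r2) - math.atanh(r1)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))


def steiger_z_compare(r12: float, r13: float, r23: float, n: int) -> float:
    """Steiger's z for two dependent correlations sharing one variable.

    Compares r13 against r12 measured on the same sample of size n,
    accounting for the correlation r23 between the non-shared variables.
    Positive when r13 exceeds r12.  Provided as the dependent-sample
    alternative; the independent-samples test is the default elsewhere.
    """
    if n <= 3:
        raise ValueError("sample size must exceed 3")
    for r in (r12, r13):
        if abs(r) >= 1:
            raise ValueError("Fisher transform is infinite at |r| = 1")
    z12, z13 = math.atanh(r12), math.atanh(r13)
    rbar = (r12 + r13) / 2
    cov = (r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)) / (
        (1 - rbar**2) ** 2
    )
    return (z13 - z12) * math.sqrt((n - 3) / (2 * (1 - cov)))


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(scores: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(row sums)).

    Complete-case rows only; requires >= 2 items and >= 3 complete rows.
    """
    data = np.asarray(scores, dtype=float)
    data = data[np.all(np.isfinite(data), axis=1)]
    n, k = data.shape
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if n < 3:
        raise ValueError("alpha requires at least 3 complete rows")
    item_var = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


def cronbach_alpha_from_cov(cov: np.ndarray | pd.DataFrame) -> float:
    """Alpha directly from an item covariance matrix: k/(k-1) (1 - tr C / sum C)."""
    C = np.asarray(cov, dtype=float)
    k = C.shape[0]
    if C.shape != (k, k) or k < 2:
        raise ValueError("need a square covariance matrix over >= 2 items")
    total = C.sum()
    if total == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1 - np.trace(C) / total))


@dataclass
class ReliabilitySet:
    alpha: float | None
    omega: float
    coefficient_h: float


def composite_reliability(
    loadings: Sequence[float],
    residual_variances: Sequence[float] | None = None,
    alpha: float | None = None,
) -> ReliabilitySet:
    """Omega and coefficient H from a standardized one-factor solution.

    omega = (sum lam)^2 / ((sum lam)^2 + sum theta) is the reliability of
    the unit-weighted composite; H = 1 / (1 + 1/sum(lam^2/(1-lam^2))) is
    the maximal reliability of the optimally weighted composite.  Under
    homogeneous loadings with theta = 1 - lam^2 the two coincide.
    """
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("standardized loadings must satisfy |lambda| < 1")
    if residual_variances is None:
        theta = 1.0 - lam**2
    else:
        theta = np.asarray(residual_variances, dtype=float)
        if theta.shape != lam.shape:
            raise ValueError("residual_variances must match loadings in length")
    s = lam.sum()
    omega = float(s**2 / (s**2 + theta.sum()))
    h = float(1.0 / (1.0 + 1.0 / np.sum(lam**2 / (1.0 - lam**2))))
    return ReliabilitySet(alpha=alpha, omega=omega, coefficient_h=h)


# ---------------------------------------------------------------------------
# confirmatory factor analysis
# ---------------------------------------------------------------------------

@dataclass
class CFAModelSpec:
    """Loading pattern and covariance structure of a CFA model.

    Each observed variable loads on exactly one factor (no
    cross-loadings).  Factor covariances are either all free or all
    fixed to zero.  ``residual_pairs`` lists the variable pairs whose
    residuals may covary; pairs within one factor are rejected, matching
    the convention that same-factor covariance belongs to the factor.
    """

    factors: dict[str, list[str]]
    residual_pairs: list[tuple[str, str]] = field(default_factory=list)
    factor_covariances: str = "free"  # "free" | "none"

    def __post_init__(self) -> None:
        if self.factor_covariances not in ("free", "none"):
            raise ValueError("factor_covariances must be 'free' or 'none'")
        owner: dict[str, str] = {}
        for fac, inds in self.factors.items():
            if not inds:
                raise ValueError(f"factor {fac!r} has no indicators")
            for v in inds:
                if v in owner:
                    raise ValueError(f"variable {v!r} loads on more than one factor")
                owner[v] = fac
        for a, b in self.residual_pairs:
            if a not in owner or b not in owner:
                raise ValueError(f"residual pair ({a!r}, {b!r}) names an unknown variable")
            if a == b:
                raise ValueError(f"residual pair ({a!r}, {b!r}) is degenerate")
            if owner[a] == owner[b]:
                raise ValueError(
                    f"residual pair ({a!r}, {b!r}) joins two variables on factor {owner[a]!r}"
                )

    @property
    def variables(self) -> list[str]:
        return [v for inds in self.factors.values() for v in inds]


@dataclass
class CFAResult:
    spec: CFAModelSpec
    loadings: pd.Series          # standardized, indexed by variable
    factor_correlations: pd.DataFrame
    residual_variances: pd.Series  # standardized
    residual_covariances: dict[tuple[str, str], float]
    chi_square: float
    df: int
    n: int
    converged: bool
    sample_cov: pd.DataFrame
    implied_cov: pd.DataFrame
    n_free_parameters: int


def load_cfa_spec(path: str | Path) -> CFAModelSpec:
    """Parse the plain-text model spec.

    INI-style: a ``[factors]`` section maps each factor name to a
    comma-separated indicator list; an optional ``[residual_pairs]``
    section lists ``a:b`` pairs (one per key) allowed to covary; an
    optional ``factor_covariances`` key in ``[options]`` is ``free`` or
    ``none``.
    """
    parser = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        parser.read_file(fh)
    if "factors" not in parser:
        raise ValueError(f"{path}: missing [factors] section")
    factors = {
        name: [v.strip() for v in val.split(",") if v.strip()]
        for name, val in parser["factors"].items()
    }
    pairs: list[tuple[str, str]] = []
    if "residual_pairs" in parser:
        for _, val in parser["residual_pairs"].items():
            a, b = (s.strip() for s in val.split(":"))
            pairs.append((a, b))
    cov = parser.get("options", "factor_covariances", fallback="free")
    return CFAModelSpec(factors=factors, residual_pairs=pairs, factor_covariances=cov)


class _CFAParameterization:
    """Flat parameter vector <-> (Lambda, Phi, Theta) with unit factor variances."""

    def __init__(self, spec: CFAModelSpec, variables: list[str]):
        self.spec = spec
        self.variables = variables
        self.factor_names = list(spec.factors)
        self.p = len(variables)
        self.m = len(self.factor_names)
        var_ix = {v: i for i, v in enumerate(variables)}
        self.loading_slots = [
            (var_ix[v], f) for f, fac in enumerate(self.factor_names) for v in spec.factors[fac]
        ]
        self.phi_slots = (
            [(a, b) for a in range(self.m) for b in range(a + 1, self.m)]
            if spec.factor_covariances == "free"
            else []
        )
        self.resid_cov_slots = [(var_ix[a], var_ix[b]) for a, b in spec.residual_pairs]
        self.n_free = (
            len(self.loading_slots) + len(self.phi_slots) + self.p + len(self.resid_cov_slots)
        )

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nl, nphi, p = len(self.loading_slots), len(self.phi_slots), self.p
        lam = np.zeros((p, self.m))
        for (i, f), val in zip(self.loading_slots, theta[:nl]):
            lam[i, f] = val
        phi = np.eye(self.m)
        for (a, b), val in zip(self.phi_slots, theta[nl : nl + nphi]):
            phi[a, b] = phi[b, a] = val
        th = np.zeros((p, p))
        np.fill_diagonal(th, theta[nl + nphi : nl + nphi + p])
        for (i, j), val in zip(self.resid_cov_slots, theta[nl + nphi + p :]):
            th[i, j] = th[j, i] = val
        return lam, phi, th

    def start(self) -> np.ndarray:
        return np.concatenate(
            [
                np.full(len(self.loading_slots), 0.5),
                np.zeros(len(self.phi_slots)),
                np.full(self.p, 0.5),
                np.zeros(len(self.resid_cov_slots)),
            ]
        )

    def bounds(self) -> list[tuple[float | None, float | None]]:
        return (
            [(None, None)] * len(self.loading_slots)
            + [(-0.999, 0.999)] * len(self.phi_slots)
            + [(1e-6, None)] * self.p
            + [(None, None)] * len(self.resid_cov_slots)
        )


def _ml_discrepancy_and_grad(
    theta: np.ndarray, par: _CFAParameterization, S: np.ndarray, logdet_S: float
) -> tuple[float, np.ndarray]:
    lam, phi, th = par.unpack(theta)
    sigma = lam @ phi @ lam.T + th
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e12 + float(np.sum(theta**2)), 2 * theta  # push back to feasible region
    sigma_inv = np.linalg.inv(sigma)
    p = par.p
    f = logdet + float(np.trace(S @ sigma_inv)) - logdet_S - p
    # dF = tr(G dSigma) with G = Sigma^-1 (Sigma - S) Sigma^-1
    G = sigma_inv @ (sigma - S) @ sigma_inv
    g_lam = 2.0 * (G @ lam @ phi)
    g_phi = lam.T @ G @ lam
    grad = np.empty_like(theta)
    k = 0
    for i, fct in par.loading_slots:
        grad[k] = g_lam[i, fct]
        k += 1
    for a, b in par.phi_slots:
        grad[k] = 2.0 * g_phi[a, b]
        k += 1
    for i in range(p):
        grad[k] = G[i, i]
        k += 1
    for i, j in par.resid_cov_slots:
        grad[k] = 2.0 * G[i, j]
        k += 1
    return f, grad


def _prepare_sample(scores: pd.DataFrame, variables: list[str]) -> tuple[np.ndarray, int]:
    data = scores[variables].astype(float).dropna()
    n = len(data)
    if n < len(variables) + 1:
        raise ValueError(f"only {n} complete rows for {len(variables)} variables")
    S = np.cov(data.to_numpy(), rowvar=False, ddof=1)
    if np.any(np.diag(S) <= 0):
        raise ValueError("every variable needs positive variance")
    return S, n


def fit_cfa(
    scores: pd.DataFrame,
    spec: CFAModelSpec,
    standardize: bool = False,
    tol: float = 1e-10,
) -> CFAResult:
    """Fit a CFA by maximum likelihood on the complete-case covariance matrix.

    Identification fixes every factor variance to 1 with all loadings
    free.  Reported loadings and residual variances are standardized
    (rescaled by the implied standard deviations); ``standardize=True``
    fits on the correlation matrix instead, which leaves the chi-square
    unchanged up to optimization error.  Non-convergence is flagged,
    never silently replaced.
    """
    variables = spec.variables
    missing = [v for v in variables if v not in scores.columns]
    if missing:
        raise ValueError(f"score matrix lacks variable(s) {missing}")
    S, n = _prepare_sample(scores, variables)
    if standardize:
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")

    par = _CFAParameterization(spec, variables)
    p = par.p
    df = p * (p + 1) // 2 - par.n_free
    if df < 0:
        raise ValueError(f"model is not identified: {par.n_free} free parameters for "
                         f"{p * (p + 1) // 2} sample moments")

    res = optimize.minimize(
        _ml_discrepancy_and_grad,
        par.start(),
        args=(par, S, logdet_S),
        jac=True,
        method="L-BFGS-B",
        bounds=par.bounds(),
        options={"maxiter": 5000, "ftol": tol, "gtol": 1e-8},
    )
    lam, phi, th = par.unpack(res.x)
    sigma = lam @ phi @ lam.T + th
    f_min = max(float(res.fun), 0.0)
    chi_square = (n - 1) * f_min

    # standardized solution: rescale by implied standard deviations
    sd = np.sqrt(np.diag(sigma))
    lam_std = lam / sd[:, None]
    theta_std = np.diag(th) / sd**2
    # collapse the loading matrix to the per-variable loading (one factor each)
    lam_per_var = lam_std.sum(axis=1)

    resid_cov = {
        (variables[i], variables[j]): float(th[i, j] / (sd[i] * sd[j]))
        for i, j in par.resid_cov_slots
    }
    return CFAResult(
        spec=spec,
        loadings=pd.Series(lam_per_var, index=variables, name="loading"),
        factor_correlations=pd.DataFrame(phi, index=par.factor_names, columns=par.factor_names),
        residual_variances=pd.Series(theta_std, index=variables, name="residual_variance"),
        residual_covariances=resid_cov,
        chi_square=chi_square,
        df=df,
        n=n,
        converged=bool(res.success),
        sample_cov=pd.DataFrame(S, index=variables, columns=variables),
        implied_cov=pd.DataFrame(sigma, index=variables, columns=variables),
        n_free_parameters=par.n_free,
    )


def independence_model(scores: pd.DataFrame, variables: Sequence[str]) -> tuple[float, int, int]:
    """Baseline model chi-square, df and n: Sigma = diag(S) in closed form.

    F_b = ln|diag S| + p - ln|S| - p = -ln|R|, so chi-square_b =
    -(n - 1) ln|R| with df_b = p(p-1)/2.
    """
    variables = list(variables)
    S, n = _prepare_sample(scores, variables)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("sample correlation matrix is not positive definite")
    p = len(variables)
    return float(-(n - 1) * logdet_R), p * (p - 1) // 2, n


@dataclass
class FitIndices:
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    tli: float
    srmr: float
    chi_square: float
    df: int
    baseline_chi_square: float
    baseline_df: int
    note: str = ""


def rmsea_from_chi2(chi_square: float, df: int, n: int) -> float:
    """RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))."""
    if df <= 0:
        return 0.0
    return math.sqrt(max(chi_square - df, 0.0) / (df * (n - 1)))


def rmsea_confidence_interval(
    chi_square: float, df: int, n: int, level: float = 0.90
) -> tuple[float, float]:
    """RMSEA interval from the noncentral chi-square noncentrality bounds.

    The lower (upper) bound solves P(X <= chi2 | df, nc) = (1 +- level)/2
    for the noncentrality nc, then maps nc to the RMSEA scale.
    """
    if df <= 0:
        return (0.0, 0.0)
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def _solve(target: float) -> float:
        if stats.chi2.cdf(chi_square, df) < target:
            return 0.0
        hi = max(chi_square, 1.0)
        while stats.ncx2.cdf(chi_square, df, hi) > target:
            hi *= 2
            if hi > 1e8:  # pragma: no cover
                break
        return optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi_square, df, nc) - target, 1e-12, hi
        )

    nc_lo, nc_hi = _solve(lo_q), _solve(hi_q)
    scale = df * (n - 1)
    return (math.sqrt(nc_lo / scale), math.sqrt(nc_hi / scale))


def _srmr(S: np.ndarray, sigma: np.ndarray) -> float:
    d = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices_from(resid)  # includes the diagonal
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def fit_indices(result: CFAResult, baseline: tuple[float, int, int] | None = None) -> FitIndices:
    """Derive RMSEA (with 90% CI), CFI, TLI and SRMR from a fitted model.

    ``baseline`` is the independence-model (chi-square, df, n) on the
    same data; computed in closed form from the stored sample covariance
    when omitted.  Whenever chi-square <= df the indices take their
    perfect-fit values (RMSEA 0, CFI 1).
    """
    chi2, df, n = result.chi_square, result.df, result.n
    if baseline is None:
        d = np.sqrt(np.diag(result.sample_cov.to_numpy()))
        R = result.sample_cov.to_numpy() / np.outer(d, d)
        _, logdet_R = np.linalg.slogdet(R)
        p = len(result.loadings)
        baseline = (float(-(n - 1) * logdet_R), p * (p - 1) // 2, n)
    chi2_b, df_b, _ = baseline

    note = ""
    if df <= 0:
        rmsea, ci = 0.0, (0.0, 0.0)
        note = "saturated model (df = 0): RMSEA fixed at 0 by convention"
    else:
        rmsea = rmsea_from_chi2(chi2, df, n)
        ci = rmsea_confidence_interval(chi2, df, n)

    # optimization noise can leave chi2 a hair above df at a perfect fit
    ncp = chi2 - df if chi2 - df > 1e-8 else 0.0
    denom = max(chi2_b - df_b, ncp, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - ncp / denom
    if df_b > 0 and chi2_b / df_b > 1 and df > 0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = 1.0
    srmr = _srmr(result.sample_cov.to_numpy(), result.implied_cov.to_numpy())
    return FitIndices(
        rmsea=rmsea,
        rmsea_ci=ci,
        cfi=cfi,
        tli=tli,
        srmr=srmr,
        chi_square=chi2,
        df=df,
        baseline_chi_square=chi2_b,
        baseline_df=df_b,
        note=note,
    )
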