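"""Firth-penalized logistic regression and the gene-level burden LRT.

Model
-----
For binary outcome :math:`y_i` (1 = case) and design row :math:`x_i`, the
logistic model has :math:`\\pi_i = \\operatorname{logit}^{-1}(x_i^T \\beta)`
and log-likelihood :math:`l(\\beta)`.  Firth's bias correction maximizes the
penalized log-likelihood

.. math:: l^*(\\beta) = l(\\beta) + \\tfrac12 \\log \\det I(\\beta),

where :math:`I(\\beta) = X^T W X` with :math:`W = \\mathrm{diag}(\\pi_i(1-\\pi_i))`
is the Fisher information — a Jeffreys-prior penalty that keeps estimates
finite and bias-reduced even under complete separation (e.g. a gene with
carriers only among cases).  The maximizer solves the modified score

.. math:: U^*_j(\\beta) = \\sum_i (y_i - \\pi_i + h_i(\\tfrac12 - \\pi_i)) x_{ij} = 0,

with :math:`h_i` the diagonal of the hat matrix
:math:`H = W^{1/2} X (X^T W X)^{-1} X^T W^{1/2}`; Newton steps
:math:`I^{-1} U^*` with step-halving guarantee monotone ascent of
:math:`l^*`.

For a design of intercept + carrier indicator only, the Firth estimate of the
carrier log-odds ratio equals the log odds ratio of the 2x2 carrier-by-status
table with 0.5 added to every cell.

The per-gene test is a penalized *profile* likelihood-ratio test: the null
fit pins the carrier coefficient at 0 and re-maximizes the remaining
parameters under the full design's penalty, so both likelihoods carry the
same information determinant and the statistic
:math:`2(l^*_{full} - l^*_{null})` (clipped at 0) is :math:`\\chi^2_1`
calibrated.  (Letting each model keep its own, lower-dimensional penalty
adds the systematically positive offset
:math:`\\log\\det I_{full}/\\det I_{null}` to the statistic and inflates
type-I error several-fold; the profile construction is what calibrated
Firth implementations use.)  Family-wise error is controlled by Bonferroni
over the genes eligible for testing (>= 5 case carriers by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .errors import ConfigError
from .qualify import CarrierMatrix, gene_test_eligibility


@dataclass(frozen=True)
class FirthOptions:
    """Newton-iteration controls.

    ``tol`` bounds the step norm at convergence; ``gtol`` bounds the modified
    score.  The score tolerance is looser because designs containing a
    single-observation indicator (a gene with exactly one carrier) give that
    observation hat-diagonal exactly 1 and the penalized likelihood an
    extreme higher-order curvature there: the analytic score plateaus around
    1e-6 while the estimate itself is stable to well below 1e-8.
    """

    tol: float = 1e-8
    gtol: float = 1e-5
    max_iter: int = 100
    max_halvings: int = 25


@dataclass
class FirthFit:
    """A fitted penalized logistic model."""

    beta: np.ndarray
    penalized_loglik: float
    hat_diagonals: np.ndarray
    iterations: int
    converged: bool
    columns: list[str] = field(default_factory=list)


def _check_design(X: np.ndarray, y: np.ndarray, columns: list[str] | None) -> list[str]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigError("X must be 2-dimensional")
    n, p = X.shape
    names = list(columns) if columns is not None else [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ConfigError("column names do not match design width")
    if not np.isfinite(X).all():
        raise ConfigError("X contains non-finite entries")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigError("y must be binary 0/1")
    # rank check via QR, naming the collinear columns
    if p > 0:
        R = np.linalg.qr(X, mode="r")
        diag = np.abs(np.diag(R))
        bad = diag < max(n, p) * np.finfo(float).eps * (diag.max() if diag.max() > 0 else 1.0)
        if bad.any():
            names_bad = [names[j] for j in np.flatnonzero(bad)]
            raise ConfigError(f"design is rank deficient; collinear columns: {names_bad}")
    return names


def penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """l(beta) + 0.5 * logdet(X' W X), computed in log space (no overflow)."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    pi = expit(eta)
    w = pi * (1.0 - pi)
    XtWX = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    options: FirthOptions | None = None,
    columns: list[str] | None = None,
    fixed: tuple[int, ...] = (),
) -> FirthFit:
    """Maximize the Firth-penalized likelihood by Newton iteration.

    Starts at beta = 0; each step solves I(beta) delta = U*(beta) and halves
    the step until the penalized log-likelihood does not decrease.
    Convergence requires both max |U*| < gtol and step norm < tol.

    ``fixed`` pins the listed coefficients at 0 while keeping the full
    design's penalty (the constrained fit of the penalized profile LRT).
    """
    opts = options or FirthOptions()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = _check_design(X, y, columns)
    n, p = X.shape
    free = np.ones(p, dtype=bool)
    for j in fixed:
        free[j] = False

    # Fit on an internally standardized design Z with X = Z @ A for an exact
    # invertible A (centering absorbed into a constant column when present,
    # columns scaled to unit spread).  This is a pure reparameterization: the
    # penalty shifts by the constant log|det A|, so the maximizer, the hat
    # diagonals and the LRT are unchanged, while the Newton system is well
    # conditioned regardless of covariate units.
    Z, A = _standardize(X)
    gamma = np.zeros(p)
    converged = False
    h = np.zeros(n)
    it = 0
    for it in range(1, opts.max_iter + 1):
        eta = Z @ gamma
        pi = expit(eta)
        w = pi * (1.0 - pi)
        ZW = Z * w[:, None]
        info = ZW.T @ Z
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,ij->i", Z @ info_inv, Z) * w
        U = Z.T @ (y - pi + h * (0.5 - pi))
        delta = np.zeros(p)
        delta[free] = np.linalg.solve(info[np.ix_(free, free)], U[free])
        if np.max(np.abs(U[free]), initial=0.0) < opts.gtol and np.linalg.norm(delta) < opts.tol:
            converged = True
            break
        ll0 = penalized_loglik(gamma, Z, y)
        # "no decrease" up to float resolution of l* — near the optimum the
        # true improvement of a full Newton step drops below representable
        # precision and must not be rejected
        slack = 16.0 * np.finfo(float).eps * max(1.0, abs(ll0))
        step = 1.0
        for _ in range(opts.max_halvings):
            if penalized_loglik(gamma + step * delta, Z, y) >= ll0 - slack:
                break
            step *= 0.5
        gamma = gamma + step * delta
    beta = np.linalg.solve(A, gamma) if p else gamma
    return FirthFit(
        beta=beta,
        penalized_loglik=penalized_loglik(beta, X, y),
        hat_diagonals=h,
        iterations=it,
        converged=converged,
        columns=names,
    )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (Z, A) with X = Z @ A, Z centered/scaled, A invertible.

    Columns are scaled to unit standard deviation (unit RMS if constant-free
    centering is impossible); centering uses the first constant column, when
    one exists, so the transform stays exactly invertible.
    """
    n, p = X.shape
    sd = X.std(axis=0)
    const_cols = np.flatnonzero(sd == 0)
    A = np.eye(p)
    Z = X.copy()
    if const_cols.size:
        ic = int(const_cols[0])
        c = X[0, ic]
        for j in range(p):
            if j == ic or sd[j] == 0:
                continue
            m, s = X[:, j].mean(), sd[j]
            Z[:, j] = (X[:, j] - m) / s
            A[j, j] = s
            A[ic, j] = m / c
    else:
        for j in range(p):
            s = np.sqrt((X[:, j] ** 2).mean())
            if s > 0:
                Z[:, j] = X[:, j] / s
                A[j, j] = s
    return Z, A


def firth_lrt(
    X_full: np.ndarray,
    y: np.ndarray,
    tested_column: int = 1,
    options: FirthOptions | None = None,
    columns: list[str] | None = None,
) -> tuple[float, float, FirthFit, FirthFit]:
    """Penalized profile likelihood-ratio test for one design column.

    The null fit pins the tested coefficient at 0 and re-maximizes the
    remaining parameters under the full design's penalty.  A constant tested
    column makes the models coincide: statistic 0, p = 1.
    Returns (statistic, p, full fit, null fit).
    """
    X_full = np.asarray(X_full, dtype=float)
    col = X_full[:, tested_column]
    if np.ptp(col) == 0.0:
        # no variation to test; drop the degenerate column for a clean fit
        X_red = np.delete(X_full, tested_column, axis=1)
        names = None
        if columns is not None:
            names = [c for j, c in enumerate(columns) if j != tested_column]
        null = fit_firth(X_red, y, options, names)
        return 0.0, 1.0, null, null
    full = fit_firth(X_full, y, options, columns)
    null = fit_firth(X_full, y, options, columns, fixed=(tested_column,))
    stat = 2.0 * (full.penalized_loglik - null.penalized_loglik)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=1))
    return stat, p, full, null


def test_all_genes(
    carrier_matrix: CarrierMatrix,
    covariates: pd.DataFrame,
    samples: pd.DataFrame,
    min_case_carriers: int = 5,
    options: FirthOptions | None = None,
) -> pd.DataFrame:
    """Per-gene Firth burden LRT with covariate adjustment.

    ``covariates`` is a samples x covariate DataFrame indexed by sample_id
    (typically PC1..PC5 and age); the design per gene is
    [intercept, carrier, covariates...], and each gene gets its own full and
    carrier-constrained null fit.  Returns one row per gene in the carrier
    matrix: carrier counts, carrier log-odds, LRT statistic, p, eligibility
    and convergence flags.
    """
    sample_ids = list(carrier_matrix.indicators.columns)
    if list(samples["sample_id"]) != sample_ids:
        raise ConfigError("carrier matrix and sample sheet are out of order")
    missing = [s for s in sample_ids if s not in covariates.index]
    if missing:
        raise ConfigError(f"covariates missing for samples: {missing[:5]}")
    cov = covariates.loc[sample_ids]
    if cov.isna().any().any():
        raise ConfigError("covariates contain missing values")
    y = (samples["phenotype"].to_numpy() == "case").astype(float)
    n = len(y)
    C = cov.to_numpy(dtype=float)
    eligible = set(gene_test_eligibility(carrier_matrix, min_case_carriers))

    counts = carrier_matrix.counts.set_index("gene")
    rows = []
    for gene in carrier_matrix.genes:
        carrier = (carrier_matrix.indicators.loc[gene].to_numpy() > 0).astype(float)
        names = ["intercept", "carrier", *cov.columns]
        if carrier.sum() == 0 or carrier.sum() == n:
            # constant carrier column: nested models coincide
            stat, p = 0.0, 1.0
            beta_carrier, conv = 0.0, True
        else:
            X = np.column_stack([np.ones(n), carrier, C])
            stat, p, full, null = firth_lrt(X, y, 1, options, names)
            beta_carrier = float(full.beta[1])
            conv = bool(full.converged and null.converged)
        rows.append(
            {
                "gene": gene,
                "case_carriers": int(counts.loc[gene, "case_carriers"]),
                "control_carriers": int(counts.loc[gene, "control_carriers"]),
                "beta_carrier": beta_carrier,
                "lrt_stat": stat,
                "p_value": p,
                "eligible": gene in eligible,
                "converged": conv,
            }
        )
    res = pd.DataFrame(rows)
    return res.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def bonferroni(results: pd.DataFrame, alpha: float = 0.05) -> tuple[float, pd.DataFrame]:
    """Bonferroni correction over the eligible genes.

    threshold = alpha / n_eligible; eligible genes get
    p_corrected = min(1, p * n_eligible); ineligible genes keep their raw p
    with p_corrected = NaN (untested for FWER purposes).
    """
    n_eligible = int(results["eligible"].sum())
    if n_eligible == 0:
        raise ConfigError("no genes are eligible for multiple-testing correction")
    out = results.copy()
    out["p_corrected"] = np.where(
        out["eligible"], np.minimum(1.0, out["p_value"] * n_eligible), np.nan
    )
    return alpha / n_eligible, out
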