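"""Comparative statistics for dental complexity and tooth replacement rate.

This module houses every statistical procedure of the analysis pipeline:

* per-taxon aggregation of tooth-level complexity (OPCRavg) and the
  replacement-rate imputation rules;
* Pearson and Kendall correlation between complexity and replacement
  interval (days);
* phylogenetic signal: Blomberg's K with a permutation p-value and Pagel's
  λ with a likelihood-ratio test (λ may exceed 1 up to the PSD limit);
* phylogenetic generalized least squares (PGLS) under Brownian-motion,
  Pagel's-λ, and Ornstein–Uhlenbeck correlation structures;
* phylogenetic ANOVA with type-I sums of squares and significance by
  residual randomization (RRPP);
* non-phylogenetic group comparisons: Kruskal–Wallis omnibus plus pairwise
  permutation t, Mann–Whitney U, and two-sample Kolmogorov–Smirnov tests.

Permutation procedures are seed-reproducible and count the observed
statistic in both numerator and denominator, so no permutation p-value is
ever exactly zero.  Pairwise clade comparisons are reported without
multiplicity adjustment by default (Holm correction available as an
option).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.optimize import minimize_scalar

from .opcr import OPCRResult
from .phylo import (
    PhyloCovariance,
    PhyloTree,
    TraitVector,
    lambda_max,
    phylo_covariance,
    transform_covariance,
)

logger = logging.getLogger("toothkit.stats")

__all__ = [
    "TaxonSummary",
    "CorrelationResult",
    "SignalResult",
    "PGLSResult",
    "AnovaResult",
    "ImputationRule",
    "aggregate_taxon",
    "summaries_to_frame",
    "impute_replacement_rates",
    "default_imputation_rules",
    "pearson_test",
    "kendall_test",
    "blomberg_k",
    "pagel_lambda_signal",
    "pgls_fit",
    "phylo_anova",
    "permutation_t_test",
    "group_tests",
]

ORNITHISCHIAN_DEFAULT_RATE_DAYS = 96.0


def _inv_psd(C: np.ndarray) -> np.ndarray:
    """Inverse of a (near-)PSD covariance; ridges exactly singular input.

    Trees with zero-length terminal branches give duplicated covariance
    rows; a tiny relative ridge keeps the GLS algebra defined while
    perturbing well-conditioned problems below numerical noise.
    """
    try:
        np.linalg.cholesky(C)
        return np.linalg.inv(C)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * float(np.trace(C)) / len(C)
        logger.warning("covariance singular; adding ridge %.3g", ridge)
        return np.linalg.inv(C + ridge * np.eye(len(C)))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class TaxonSummary:
    """Per-taxon complexity (OPCRavg) and covariates."""

    taxon: str
    clade: str
    opcr_avg_3: float
    opcr_avg_5: float
    n_teeth: int = 1
    replacement_rate_days: float | None = None
    rate_source: str = "measured"
    element: str = "combined"

    def __post_init__(self) -> None:
        if self.opcr_avg_3 <= 0 or self.opcr_avg_5 <= 0:
            raise ValueError("OPCRavg values must be positive")
        if self.opcr_avg_5 > self.opcr_avg_3 + 1e-9:
            raise ValueError(
                f"{self.taxon}: OPCRavg at minimum patch 5 exceeds the "
                "3-triangle value, violating the size-filter ordering"
            )
        if self.replacement_rate_days is not None \
                and self.replacement_rate_days <= 0:
            raise ValueError("replacement_rate_days must be positive")


@dataclass
class CorrelationResult:
    method: str           # "pearson" | "kendall"
    estimate: float       # r or tau-b
    statistic: float      # t (pearson) or z (kendall)
    p: float
    n: int


@dataclass
class SignalResult:
    metric: str           # "blomberg_k" | "pagel_lambda"
    estimate: float
    p: float
    n: int
    n_perm: int | None = None
    logL_fit: float | None = None
    logL_null: float | None = None


@dataclass
class PGLSResult:
    model: str
    slope: float
    intercept: float
    slope_se: float
    t: float
    p: float
    n: int
    fitted_param: float | None = None   # lambda-hat or alpha-hat
    logL: float | None = None


@dataclass
class AnovaResult:
    F: float
    p_perm: float
    iterations: int
    df_effect: int
    df_resid: int
    ss_type: str = "I"


@dataclass
class ImputationRule:
    """How to fill one taxon's missing replacement rate.

    ``kind="donor_mean"`` averages the known rates of ``donors``;
    ``kind="constant"`` uses ``value`` (``None`` resolves to the 96-day
    herbivorous-ornithischian default when the recipient is an
    ornithischian).
    """

    kind: str
    donors: tuple[str, ...] = ()
    value: float | None = None


# ---------------------------------------------------------------------------
# aggregation & imputation
# ---------------------------------------------------------------------------

def aggregate_taxon(per_tooth: list[OPCRResult], metadata: pd.DataFrame,
                    split_elements: bool = False) -> list[TaxonSummary]:
    """Average tooth-level OPCR into per-taxon OPCRavg, both thresholds.

    ``per_tooth`` holds results at minimum patch sizes 3 and 5 for every
    mesh; ``metadata`` maps ``mesh_name`` to taxon, clade, element and
    (optionally) replacement rate.  The mean is unweighted over all teeth,
    worn and unworn alike.  With ``split_elements`` the taxon is summarised
    per tooth-bearing element (upper jaw vs dentary) instead of combined.
    """
    md = metadata.set_index("mesh_name")
    rows: dict[tuple[str, str], dict[int, list[float]]] = {}
    meta_first: dict[tuple[str, str], pd.Series] = {}
    for res in per_tooth:
        if res.mesh_name not in md.index:
            raise KeyError(f"mesh {res.mesh_name!r} missing from metadata")
        rec = md.loc[res.mesh_name]
        element = str(rec.get("element", "combined"))
        if split_elements:
            if "element" not in md.columns:
                raise ValueError(
                    "element split requested but metadata has no "
                    "'element' column"
                )
            key = (str(rec["taxon"]), element)
        else:
            key = (str(rec["taxon"]), "combined")
        rows.setdefault(key, {}).setdefault(res.min_patch_size, []) \
            .append(res.opcr)
        meta_first.setdefault(key, rec)

    out: list[TaxonSummary] = []
    for (taxon, element), by_thresh in sorted(rows.items()):
        if 3 not in by_thresh or 5 not in by_thresh:
            raise ValueError(
                f"taxon {taxon!r}: OPCR results must be present at both "
                "minimum patch sizes (3 and 5)"
            )
        rec = meta_first[(taxon, element)]
        rate = rec.get("replacement_rate_days")
        rate = None if rate is None or pd.isna(rate) else float(rate)
        out.append(TaxonSummary(
            taxon=taxon if element == "combined" else f"{taxon}_{element}",
            clade=str(rec.get("clade", "")),
            opcr_avg_3=float(np.mean(by_thresh[3])),
            opcr_avg_5=float(np.mean(by_thresh[5])),
            n_teeth=len(by_thresh[3]),
            replacement_rate_days=rate,
            rate_source=str(rec.get("rate_source", "measured")),
            element=element,
        ))
    return out


def summaries_to_frame(summaries: list[TaxonSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def default_imputation_rules(summaries: list[TaxonSummary]
                             ) -> dict[str, ImputationRule]:
    """Constant-96-day rules for ornithischians with missing rates."""
    return {
        s.taxon: ImputationRule(kind="constant", value=None)
        for s in summaries
        if s.replacement_rate_days is None and s.clade == "ornithischian"
    }


def impute_replacement_rates(summaries: list[TaxonSummary],
                             rules: dict[str, ImputationRule]
                             ) -> list[TaxonSummary]:
    """Fill missing replacement rates according to explicit per-taxon rules.

    Every imputation is logged.  A taxon with a missing rate and no
    applicable rule stays missing (downstream rate analyses exclude it with
    a warning).
    """
    known = {s.taxon: s.replacement_rate_days for s in summaries
             if s.replacement_rate_days is not None}
    out: list[TaxonSummary] = []
    for s in summaries:
        if s.replacement_rate_days is not None or s.taxon not in rules:
            if s.replacement_rate_days is None:
                logger.warning(
                    "taxon %r: no replacement rate and no imputation rule; "
                    "left missing", s.taxon)
            out.append(replace(s))
            continue
        rule = rules[s.taxon]
        if rule.kind == "donor_mean":
            donor_rates = [known[d] for d in rule.donors if d in known]
            if not donor_rates:
                logger.warning("taxon %r: no donor rates available; "
                               "left missing", s.taxon)
                out.append(replace(s))
                continue
            value = float(np.mean(donor_rates))
        elif rule.kind == "constant":
            if rule.value is not None:
                value = float(rule.value)
            elif s.clade == "ornithischian":
                value = ORNITHISCHIAN_DEFAULT_RATE_DAYS
            else:
                logger.warning(
                    "taxon %r: constant rule without value only applies to "
                    "ornithischians; left missing", s.taxon)
                out.append(replace(s))
                continue
        else:
            raise ValueError(f"unknown imputation rule kind {rule.kind!r}")
        logger.info("imputed replacement rate for %r: %.4g days (%s)",
                    s.taxon, value, rule.kind)
        out.append(replace(s, replacement_rate_days=value,
                           rate_source="imputed"))
    return out


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _aligned_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, TraitVector) and isinstance(y, TraitVector):
        y = y.reordered(x.taxon_order)
        return x.values, y.values
    return np.asarray(x, float), np.asarray(y, float)


def pearson_test(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the t-test on n−2 df."""
    xv, yv = _aligned_xy(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError("pearson test needs n >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(xv, yv)
    if abs(r) < 1.0:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    else:
        t = math.copysign(math.inf, r)
    return CorrelationResult("pearson", float(r), float(t), float(p), n)


def kendall_test(x, y) -> CorrelationResult:
    """Kendall's τ-b with the tie-corrected normal approximation.

    The z statistic and two-sided p follow the classical variance of the
    concordance score S under ties (the large-sample test R's ``cor.test``
    reports for tied data).
    """
    xv, yv = _aligned_xy(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError("kendall test needs n >= 3")
    if len(np.unique(xv)) == 1 or len(np.unique(yv)) == 1:
        raise ValueError("all-tied variable")
    tau = float(sps.kendalltau(xv, yv, variant="b").statistic)

    # concordance score and its variance under the null, with tie terms
    S = 0
    for i, j in itertools.combinations(range(n), 2):
        S += int(np.sign(xv[i] - xv[j]) * np.sign(yv[i] - yv[j]))
    t_counts = np.array(list(pd.Series(xv).value_counts()), dtype=float)
    u_counts = np.array(list(pd.Series(yv).value_counts()), dtype=float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(t_counts * (t_counts - 1) * (2 * t_counts + 5)))
    vu = float(np.sum(u_counts * (u_counts - 1) * (2 * u_counts + 5)))
    v1 = float(np.sum(t_counts * (t_counts - 1))
               * np.sum(u_counts * (u_counts - 1))) / (2 * n * (n - 1))
    v2 = float(np.sum(t_counts * (t_counts - 1) * (t_counts - 2))
               * np.sum(u_counts * (u_counts - 1) * (u_counts - 2))) \
        / (9 * n * (n - 1) * (n - 2))
    var_S = (v0 - vt - vu) / 18.0 + v1 + v2
    z = S / math.sqrt(var_S)
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationResult("kendall", tau, float(z), float(min(p, 1.0)), n)


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

def _tree_trait(tree: PhyloTree, trait: TraitVector
                ) -> tuple[np.ndarray, np.ndarray]:
    C = phylo_covariance(tree)
    y = trait.reordered(C.taxon_order).values
    return C.matrix, y


def blomberg_k(tree: PhyloTree, trait: TraitVector, n_perm: int = 999,
               seed: int = 0) -> SignalResult:
    """Blomberg's K with a one-tailed tip-permutation significance test.

    K compares the observed ratio of the raw mean squared deviation from
    the phylogenetic (GLS) mean to the GLS mean squared error with the
    ratio expected under Brownian motion on the same tree; K=1 is the BM
    expectation.  The p-value is the fraction of tip-label permutations
    (observed included) whose GLS mean squared error is at most the
    observed one — low MSE means the tree explains the data well.
    """
    C, y = _tree_trait(tree, trait)
    n = len(y)
    if n < 4:
        raise ValueError("blomberg_k needs >= 4 tips")
    Ci = _inv_psd(C)
    one = np.ones(n)
    denom = one @ Ci @ one

    def mse_pair(vec: np.ndarray) -> tuple[float, float]:
        ahat = (one @ Ci @ vec) / denom
        r = vec - ahat
        return float(r @ r) / (n - 1), float(r @ Ci @ r) / (n - 1)

    mse0, mse = mse_pair(y)
    expected = (float(np.trace(C)) - n / denom) / (n - 1)
    K = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    perm_mse = np.empty(n_perm)
    Ci1 = Ci @ one
    for b in range(n_perm):
        yp = y[rng.permutation(n)]
        ahat = (Ci1 @ yp) / denom
        r = yp - ahat
        perm_mse[b] = (r @ Ci @ r) / (n - 1)
    p = (1 + int(np.sum(perm_mse <= mse))) / (n_perm + 1)
    return SignalResult("blomberg_k", float(K), float(p), n, n_perm=n_perm)


def _lambda_loglik(C: np.ndarray, y: np.ndarray, lam: float) -> float:
    M = lam * C
    np.fill_diagonal(M, C.diagonal())
    n = len(y)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    Mi = _inv_psd(M)
    one = np.ones(n)
    ahat = (one @ Mi @ y) / (one @ Mi @ one)
    r = y - ahat
    s2 = float(r @ Mi @ r) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)


def pagel_lambda_signal(tree: PhyloTree, trait: TraitVector) -> SignalResult:
    """ML estimate of Pagel's λ with a 1-df likelihood-ratio test vs λ=0.

    λ is optimized over [0, λ_max] where λ_max is the largest value keeping
    the transformed covariance positive definite, so estimates above 1 are
    admissible on non-star trees.
    """
    C, y = _tree_trait(tree, trait)
    if len(y) < 4:
        raise ValueError("pagel_lambda_signal needs >= 4 tips")
    lam_hi = lambda_max(PhyloCovariance(C, ["t"] * len(y)))
    res = minimize_scalar(
        lambda lam: -_lambda_loglik(C, y, lam),
        bounds=(0.0, max(lam_hi - 1e-9, 1e-9)), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"lambda optimizer failed: {res.message}")
    lam_hat = float(res.x)
    logl_fit = -float(res.fun)
    # the bounded optimizer avoids the exact endpoints; snap if better
    for cand in (0.0, 1.0):
        if 0.0 <= cand <= lam_hi:
            ll = _lambda_loglik(C, y, cand)
            if ll > logl_fit:
                lam_hat, logl_fit = cand, ll
    logl_null = _lambda_loglik(C, y, 0.0)
    lr = max(2.0 * (logl_fit - logl_null), 0.0)
    p = float(sps.chi2.sf(lr, df=1))
    return SignalResult("pagel_lambda", lam_hat, p, len(y),
                        logL_fit=logl_fit, logL_null=logl_null)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def _gls(X: np.ndarray, y: np.ndarray, M: np.ndarray
         ) -> tuple[np.ndarray, float, np.ndarray, float]:
    """GLS fit; returns (beta, rss_gls, XtMiX_inv, logdet_M)."""
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    Mi = _inv_psd(M)
    XtMiX = X.T @ Mi @ X
    if np.linalg.cond(XtMiX) > 1e12:
        raise np.linalg.LinAlgError("singular design matrix")
    XtMiX_inv = np.linalg.inv(XtMiX)
    beta = XtMiX_inv @ X.T @ Mi @ y
    r = y - X @ beta
    rss = float(r @ Mi @ r)
    return beta, rss, XtMiX_inv, logdet


def _gls_loglik(X: np.ndarray, y: np.ndarray, M: np.ndarray) -> float:
    n = len(y)
    try:
        _, rss, _, logdet = _gls(X, y, M)
    except np.linalg.LinAlgError:
        return -np.inf
    s2 = rss / n
    if s2 <= 0:
        return np.inf  # perfect fit; caller handles degenerate case
    return -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)


def pgls_fit(tree: PhyloTree, y: TraitVector, x: TraitVector,
             model: str = "bm") -> PGLSResult:
    """PGLS of y on x under a BM, Pagel's-λ, or OU correlation structure.

    For ``lambda`` and ``ou`` the structure parameter is estimated by ML
    jointly with the coefficients (profiled σ²).  The slope test uses
    t = β̂/SE(β̂) with n−2 df; with an identity correlation (star tree under
    BM) the estimates coincide with ordinary least squares.
    """
    Cbm = phylo_covariance(tree)
    yv = y.reordered(Cbm.taxon_order).values
    xv = x.reordered(Cbm.taxon_order).values
    n = len(yv)
    X = np.column_stack([np.ones(n), xv])
    fitted_param: float | None = None

    if model == "bm":
        M = Cbm.matrix
    elif model == "lambda":
        lam_hi = lambda_max(Cbm)
        res = minimize_scalar(
            lambda lam: -_gls_loglik(
                X, yv, _with_diag(lam * Cbm.matrix, Cbm.matrix.diagonal())),
            bounds=(0.0, max(lam_hi - 1e-9, 1e-9)), method="bounded",
            options={"xatol": 1e-8},
        )
        fitted_param = float(res.x)
        M = _with_diag(fitted_param * Cbm.matrix, Cbm.matrix.diagonal())
    elif model == "ou":
        diag = Cbm.matrix.diagonal()
        Dpat = diag[:, None] + diag[None, :] - 2 * Cbm.matrix
        scale = max(float(np.mean(diag)), 1e-12)
        res = minimize_scalar(
            lambda la: -_gls_loglik(X, yv, _ou_corr(Dpat, math.exp(la))),
            bounds=(math.log(1e-4 / scale), math.log(100.0 / scale)),
            method="bounded", options={"xatol": 1e-8},
        )
        fitted_param = float(math.exp(res.x))
        M = _ou_corr(Dpat, fitted_param)
    else:
        raise ValueError(f"unknown PGLS model {model!r}")

    beta, rss, XtMiX_inv, _ = _gls(X, yv, M)
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("fewer observations than parameters")
    s2 = rss / df
    scale_y = max(float(np.mean(yv**2)), 1.0)
    if s2 <= 1e-12 * scale_y:
        # degenerate: response (conditionally) constant; slope carries no
        # information against the null
        slope = float(beta[1])
        se = math.sqrt(max(s2, 0.0) * XtMiX_inv[1, 1]) or 1.0
        return PGLSResult(model, slope, float(beta[0]), se, 0.0, 1.0, n,
                          fitted_param=fitted_param)
    se = math.sqrt(s2 * XtMiX_inv[1, 1])
    t = float(beta[1]) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PGLSResult(model, float(beta[1]), float(beta[0]), se, t, p, n,
                      fitted_param=fitted_param,
                      logL=_gls_loglik(X, yv, M))


def _with_diag(M: np.ndarray, diag: np.ndarray) -> np.ndarray:
    out = M.copy()
    np.fill_diagonal(out, diag)
    return out


def _ou_corr(Dpat: np.ndarray, alpha: float) -> np.ndarray:
    M = np.exp(-alpha * Dpat)
    np.fill_diagonal(M, 1.0)
    return M


# ---------------------------------------------------------------------------
# phylogenetic ANOVA (RRPP)
# ---------------------------------------------------------------------------

def _design_matrix(x, n: int) -> np.ndarray:
    """Full-model design: intercept plus continuous column or factor
    dummies (first level as reference)."""
    arr = np.asarray(x)
    if arr.dtype.kind in "OUS":  # factor
        levels = sorted(set(arr.tolist()))
        cols = [np.asarray(arr == lev, float) for lev in levels[1:]]
        X = np.column_stack([np.ones(n)] + cols) if cols \
            else np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), arr.astype(float)])
    return X


def phylo_anova(tree: PhyloTree, y: TraitVector, x,
                iterations: int = 9999, seed: int = 0) -> AnovaResult:
    """Phylogenetic ANOVA: type-I SS F in GLS-transformed space, p by
    residual randomization (RRPP).

    The data are whitened with the inverse Cholesky factor of the BM
    covariance; the F statistic compares the effect sum of squares of the
    full model (intercept + predictor) against the residual sum of squares.
    Significance permutes the reduced-model (intercept-only) residuals,
    with the observed arrangement counted among the permutations.
    """
    C = phylo_covariance(tree)
    yv = y.reordered(C.taxon_order).values
    n = len(yv)
    if isinstance(x, TraitVector):
        xv = x.reordered(C.taxon_order).values
    else:
        xv = np.asarray(x)
        if len(xv) != n:
            raise ValueError("predictor length mismatch")
    X = _design_matrix(xv, n)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    df_effect = X.shape[1] - 1
    df_resid = n - X.shape[1]
    if df_resid <= 0 or df_effect < 1:
        raise ValueError("not enough observations for the design")

    Cm = C.matrix
    try:
        L = np.linalg.cholesky(Cm)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * float(np.trace(Cm)) / n
        L = np.linalg.cholesky(Cm + ridge * np.eye(n))
    W = np.linalg.inv(L)              # whitening transform
    yt = W @ yv
    Xt_full = W @ X
    Xt_red = W @ np.ones((n, 1))

    def hat(A: np.ndarray) -> np.ndarray:
        return A @ np.linalg.pinv(A)

    Hf, Hr = hat(Xt_full), hat(Xt_red)
    fit_r = Hr @ yt
    resid_r = yt - fit_r

    def f_stat(Y: np.ndarray) -> np.ndarray:
        # Y: (..., n) in transformed space
        rss_f = np.sum((Y - Y @ Hf.T) ** 2, axis=-1)
        rss_r = np.sum((Y - Y @ Hr.T) ** 2, axis=-1)
        return ((rss_r - rss_f) / df_effect) / (rss_f / df_resid)

    F_obs = float(f_stat(yt[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(iterations)])
    Y = fit_r[None, :] + resid_r[perms]
    F_perm = f_stat(Y)
    p = (1 + int(np.sum(F_perm >= F_obs))) / (iterations + 1)
    return AnovaResult(F=F_obs, p_perm=float(p), iterations=iterations,
                       df_effect=df_effect, df_resid=df_resid)


# ---------------------------------------------------------------------------
# non-phylogenetic group tests
# ---------------------------------------------------------------------------

def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb)))


def permutation_t_test(a, b, replicates: int = 9999, seed: int = 0
                       ) -> dict[str, float]:
    """Two-sided permutation test on the pooled-variance t statistic.

    When the number of distinct label assignments is at most ``replicates``
    the full enumeration is used (exact p, observed assignment included);
    otherwise ``replicates`` random shuffles are drawn and the observed
    statistic is counted in both numerator and denominator.  The analytic
    Welch p is reported alongside for reference.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, n = len(a), len(a) + len(b)
    pooled = np.concatenate([a, b])
    t_obs = _pooled_t(a, b)
    n_comb = math.comb(n, na)
    if n_comb <= replicates:
        count = 0
        idx_all = frozenset(range(n))
        for comb in itertools.combinations(range(n), na):
            ia = np.fromiter(comb, int, na)
            ib = np.fromiter(sorted(idx_all - set(comb)), int, n - na)
            if abs(_pooled_t(pooled[ia], pooled[ib])) >= abs(t_obs) - 1e-12:
                count += 1
        p = count / n_comb
        exact = True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(replicates):
            perm = rng.permutation(n)
            tp = _pooled_t(pooled[perm[:na]], pooled[perm[na:]])
            if abs(tp) >= abs(t_obs) - 1e-12:
                count += 1
        p = (1 + count) / (replicates + 1)
        exact = False
    welch = sps.ttest_ind(a, b, equal_var=False)
    return {"t": t_obs, "p": float(p), "exact": exact,
            "welch_t": float(welch.statistic), "welch_p": float(welch.pvalue)}


def group_tests(values, grouping, replicates: int = 9999, seed: int = 0,
                holm: bool = False) -> dict:
    """Omnibus and pairwise distribution comparisons between clades.

    Runs a Kruskal–Wallis test across all groups, then for each unordered
    pair a permutation t-test, a Mann–Whitney U, and a two-sample
    Kolmogorov–Smirnov test, all two-sided.  P-values are reported per test
    without multiplicity adjustment unless ``holm=True``.  Pairs involving
    a group with fewer than two members are skipped with a warning.
    """
    values = np.asarray(values, float)
    grouping = np.asarray(grouping)
    groups = {g: values[grouping == g] for g in sorted(set(grouping.tolist()))}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    usable = {g: v for g, v in groups.items() if len(v) >= 2}
    report: dict = {"groups": {g: len(v) for g, v in groups.items()}}
    if len(usable) >= 2:
        kw = sps.kruskal(*usable.values())
        report["kruskal"] = {"H": float(kw.statistic),
                            "p": float(kw.pvalue)}
    pairwise: dict = {}
    rng = np.random.default_rng(seed)
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        a, b = groups[g1], groups[g2]
        if len(a) < 2 or len(b) < 2:
            logger.warning("pair (%s, %s) skipped: group with < 2 members",
                           g1, g2)
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        perm = permutation_t_test(a, b, replicates=replicates, seed=sub_seed)
        mwu = sps.mannwhitneyu(a, b, alternative="two-sided")
        ks = sps.ks_2samp(a, b)
        pairwise[(g1, g2)] = {
            "perm_t": perm,
            "mannwhitney": {"U": float(mwu.statistic),
                            "p": float(mwu.pvalue)},
            "ks": {"D": float(ks.statistic), "p": float(ks.pvalue)},
        }
    if holm and pairwise:
        for test_key, picker in [("perm_t", lambda d: d["perm_t"]["p"]),
                                 ("mannwhitney",
                                  lambda d: d["mannwhitney"]["p"]),
                                 ("ks", lambda d: d["ks"]["p"])]:
            pairs = list(pairwise)
            ps = np.array([picker(pairwise[k]) for k in pairs])
            order = np.argsort(ps)
            m = len(ps)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * ps[idx])
                adj[idx] = min(running, 1.0)
            for k, padj in zip(pairs, adj):
                pairwise[k][test_key + "_holm_p"] = float(padj)
    report["pairwise"] = pairwise
    return report
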