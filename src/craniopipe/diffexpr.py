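"""Covariate-adjusted differential expression with moderated t-statistics.

Per gene, log2 expression is modeled on group indicators (control as the
reference level) plus age in months and sex (0 = female, 1 = male).  The
array processing batch enters either as

* ``gls`` (default): a common-correlation generalized least squares in the
  style of limma's duplicateCorrelation — a consensus intra-batch
  correlation is estimated by pooling per-gene moment estimates, then every
  gene is fit by GLS under the block-equicorrelated covariance; or
* ``fixed``: ordinary least squares with batch indicator columns; or
* ``none``: batch ignored (for data without batch structure).

Gene-wise residual variances are shrunk toward a common prior by fitting a
scaled inverse-chi-square prior (s0^2, d0) to the variances via moment
matching on log s^2 (Smyth-style empirical Bayes); the moderated t uses the
posterior variance and d0 + residual df degrees of freedom.  P-values are
adjusted across genes by Benjamini-Hochberg.

Effect sizes are reported both as log2 fold changes and as signed percent
change, ``sign(lfc) * (2^|lfc| - 1) * 100``; significance ("sig") applies
the raw moderated p-value against the 0.05 threshold and "large" requires
|% change| strictly greater than 50 — both thresholds configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import CASE_GROUPS, DataError, GeneMatrix, validate_annotation

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelError",
    "DEFAULT_CONTRASTS",
    "fit_gene_models",
    "moderate_variances",
    "bh_adjust",
    "lfc_to_pct",
    "de_analysis",
    "parse_contrasts",
]

#: All seven contrasts of the study: three case-vs-control, the pooled
#: all-cases-vs-control, and the three case-vs-case comparisons.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("coronal", "control"),
    ("metopic", "control"),
    ("sagittal", "control"),
    ("all", "control"),
    ("coronal", "metopic"),
    ("coronal", "sagittal"),
    ("metopic", "sagittal"),
)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """What to fit and how to threshold the results."""

    contrasts: tuple = DEFAULT_CONTRASTS
    batch_mode: str = "gls"  # "gls" | "fixed" | "none"
    sig_threshold: float = 0.05
    large_threshold: float = 50.0
    sig_on_adjusted: bool = False  # significance on raw moderated p by default

    def validate(self) -> None:
        if self.batch_mode not in ("gls", "fixed", "none"):
            raise ModelError(f"unknown batch_mode {self.batch_mode!r}")
        if self.sig_threshold <= 0 or self.large_threshold <= 0:
            raise ModelError("thresholds must be positive")
        for a, b in self.contrasts:
            groups = set(CASE_GROUPS) | {"control", "all"}
            if a not in groups or b not in groups:
                raise ModelError(f"unknown contrast ({a}, {b})")


def parse_contrasts(text: str) -> tuple[tuple[str, str], ...]:
    """Parse ``"coronal:control,metopic:control"`` into contrast pairs."""
    pairs = []
    for item in text.split(","):
        a, _, b = item.strip().partition(":")
        if not b:
            raise ModelError(f"malformed contrast {item!r}; expected groupA:groupB")
        pairs.append((a, b))
    return tuple(pairs)


# --------------------------------------------------------------------------
# design matrices and fitting
# --------------------------------------------------------------------------

def _design_matrix(
    annotation: pd.DataFrame, pooled: bool, batch_fixed: bool
) -> tuple[np.ndarray, list[str]]:
    n = len(annotation)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    group = annotation["group"].to_numpy()
    if pooled:
        cols.append((group != "control").astype(float))
        names.append("case")
    else:
        for g in CASE_GROUPS:
            cols.append((group == g).astype(float))
            names.append(g)
    cols.append(annotation["age_months"].to_numpy(float))
    names.append("age_months")
    cols.append(annotation["sex"].to_numpy(float))
    names.append("sex")
    if batch_fixed:
        levels = sorted(set(annotation["batch"]))
        for b in levels[1:]:  # first level is the reference
            cols.append((annotation["batch"].to_numpy() == b).astype(float))
            names.append(f"batch[{b}]")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    collinear = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        fit, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ fit
        denom = ((X[:, j] - X[:, j].mean()) ** 2).sum() or 1.0
        if (resid**2).sum() / denom < 1e-10:
            collinear.append(names[j])
    raise ModelError(f"design matrix is rank deficient; collinear columns: {collinear}")


def _consensus_batch_correlation(
    Y: np.ndarray, X: np.ndarray, batch: np.ndarray
) -> float:
    """Pooled moment estimate of the intra-batch correlation.

    Fits the fixed effects by OLS, then computes a one-way-ANOVA intraclass
    correlation of the residuals by batch for every gene and pools the
    per-gene estimates on the Fisher z scale (duplicateCorrelation-style,
    without REML).
    """
    beta = Y @ np.linalg.pinv(X).T
    E = Y - beta @ X.T
    levels, idx = np.unique(batch, return_inverse=True)
    B = len(levels)
    n = len(batch)
    if B < 2:
        return 0.0
    sizes = np.bincount(idx).astype(float)
    M = np.zeros((n, B))
    M[np.arange(n), idx] = 1.0
    means = (E @ M) / sizes  # (G, B)
    grand = E.mean(axis=1, keepdims=True)
    ssb = (sizes * (means - grand) ** 2).sum(axis=1)
    ssw = (E**2).sum(axis=1) - (sizes * means**2).sum(axis=1)
    msb = ssb / (B - 1)
    msw = ssw / max(n - B, 1)
    n0 = (n - (sizes**2).sum() / n) / (B - 1)
    denom = msb + (n0 - 1) * msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msb - msw) / np.where(denom > 0, denom, 1.0), 0.0)
    icc = np.clip(icc, -0.95, 0.95)
    rho = float(np.tanh(np.mean(np.arctanh(icc))))
    # block-equicorrelation requires rho > -1/(m-1); batch effects are
    # non-negative correlations, so clip at zero for the whitening step
    return max(rho, 0.0)


def _whitening_matrix(batch: np.ndarray, rho: float) -> np.ndarray:
    """Symmetric inverse square root of the block-equicorrelated covariance."""
    n = len(batch)
    W = np.zeros((n, n))
    for level in np.unique(batch):
        members = np.flatnonzero(batch == level)
        m = len(members)
        P = np.full((m, m), -1.0 / m)
        np.fill_diagonal(P, 1.0 - 1.0 / m)
        J = np.full((m, m), 1.0 / m)
        block = P / math.sqrt(1.0 - rho) + J / math.sqrt(1.0 - rho + m * rho)
        W[np.ix_(members, members)] = block
    return W


@dataclass
class ModelFit:
    """Per-gene linear-model fit: coefficients, residual variances, design."""

    coefficients: pd.DataFrame  # genes x coefficient names
    cov_unscaled: np.ndarray  # (p, p) = (X'X)^-1 of the (whitened) design
    s2: pd.Series  # gene-wise residual variance
    df_residual: float
    coef_names: list[str]
    batch_mode: str
    rho: float | None = None  # consensus intra-batch correlation (gls mode)

    def contrast_vector(self, contrast: tuple[str, str]) -> np.ndarray:
        a, b = contrast
        c = np.zeros(len(self.coef_names))

        def coef_of(g: str) -> np.ndarray:
            v = np.zeros(len(self.coef_names))
            if g == "control":
                return v
            name = "case" if g == "all" else g
            if name not in self.coef_names:
                raise ModelError(f"model has no coefficient for group {g!r}")
            v[self.coef_names.index(name)] = 1.0
            return v

        return coef_of(a) - coef_of(b)

    def contrast(self, contrast: tuple[str, str]) -> tuple[pd.Series, float]:
        """(log2 fold change per gene, unscaled standard error) for a contrast.

        The unscaled SE is sqrt(c' (X'X)^-1 c); multiply by a residual (or
        posterior) standard deviation to get the SE of the estimate.
        """
        c = self.contrast_vector(contrast)
        lfc = self.coefficients.to_numpy() @ c
        use = float(np.sqrt(c @ self.cov_unscaled @ c))
        return pd.Series(lfc, index=self.coefficients.index), use


def fit_gene_models(
    genes: GeneMatrix,
    annotation: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    *,
    pooled: bool = False,
) -> ModelFit:
    """Fit the per-gene expression model for every gene at once.

    With ``pooled=True`` the three case groups collapse into a single
    "case" indicator (used for the all-cases-vs-control contrast).
    """
    spec.validate()
    annotation = validate_annotation(annotation)
    if list(genes.sample_ids) != list(annotation["sample_id"]):
        genes = GeneMatrix(values=genes.values.loc[:, annotation["sample_id"].tolist()])

    Y = genes.values.to_numpy(dtype=float)
    batch = annotation["batch"].to_numpy()
    X, names = _design_matrix(annotation, pooled=pooled, batch_fixed=spec.batch_mode == "fixed")
    _check_full_rank(X, names)

    rho = None
    if spec.batch_mode == "gls":
        rho = _consensus_batch_correlation(Y, X, batch)
        W = _whitening_matrix(batch, rho)
        X = W @ X
        Y = Y @ W.T  # W symmetric

    n, p = X.shape
    if n <= p:
        raise ModelError(f"not enough samples ({n}) for {p} model columns")
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    resid = Y - beta @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    cov_unscaled = np.linalg.inv(X.T @ X)
    return ModelFit(
        coefficients=pd.DataFrame(beta, index=genes.gene_ids, columns=names),
        cov_unscaled=cov_unscaled,
        s2=pd.Series(s2, index=genes.gene_ids),
        df_residual=float(df),
        coef_names=names,
        batch_mode=spec.batch_mode,
        rho=rho,
    )


# --------------------------------------------------------------------------
# empirical-Bayes moderation
# --------------------------------------------------------------------------

def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + step
        if np.all(-step / y < 1e-10):
            break
    return y


def moderate_variances(
    s2, df: float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene-wise variances.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the variances by
    matching the mean and variance of log s^2 against their theoretical
    values under the prior, then returns

        posterior s^2 = (d0 * s0^2 + df * s^2) / (d0 + df)

    together with the fitted hyperparameters.  If the observed spread of
    log s^2 is no larger than the chi-square sampling noise alone, d0 is
    +inf and the posterior collapses to the common variance.

    Returns
    -------
    (s2_post, d0, s0_sq)
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise DataError("variance moderation needs at least 10 genes")
    if np.any(s2 < 0) or df <= 0:
        raise DataError("variances must be >= 0 and df > 0")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array(evar)))
        s0_sq = float(math.exp(emean + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = math.inf
        s0_sq = float(s2.mean())
        post = np.full_like(s2, s0_sq)
    return post, d0, s0_sq


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lfc_to_pct(lfc: float, *, rounded: bool = False):
    """Signed percent change for a log2 fold change.

    ``sign(lfc) * (2^|lfc| - 1) * 100``; with ``rounded=True`` the value is
    rounded to the nearest integer, halves away from zero, matching how
    percent changes are conventionally printed next to log2 fold changes.
    """
    arr = np.asarray(lfc, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise DataError("log2 fold change must be finite")
    pct = np.sign(arr) * (np.exp2(np.abs(arr)) - 1.0) * 100.0
    if rounded:
        pct = np.sign(pct) * np.floor(np.abs(pct) + 0.5)
        pct = pct.astype(int)
    if np.isscalar(lfc):
        return int(pct) if rounded else float(pct)
    return pct


# --------------------------------------------------------------------------
# full differential-expression analysis
# --------------------------------------------------------------------------

def _contrast_table(
    fit: ModelFit, contrast: tuple[str, str], s2_post: np.ndarray, df_total: float,
    spec: ModelSpec,
) -> pd.DataFrame:
    lfc, use = fit.contrast(contrast)
    se = use * np.sqrt(s2_post)
    t = lfc.to_numpy() / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p_adj = bh_adjust(p)
    pct = lfc_to_pct(lfc.to_numpy())
    sig = (p_adj if spec.sig_on_adjusted else p) < spec.sig_threshold
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "pct_change": pct,
            "pct_change_int": lfc_to_pct(lfc.to_numpy(), rounded=True),
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "sig": sig,
            "large": np.abs(pct) > spec.large_threshold,
        },
        index=lfc.index,
    )
    out.index.name = "gene_id"
    return out


def de_analysis(
    genes: GeneMatrix,
    annotation: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> dict[str, pd.DataFrame]:
    """Run the full moderated differential-expression analysis.

    Returns one table per contrast, keyed ``"coronal_control"`` etc., with
    columns lfc, pct_change (exact), pct_change_int (as printed), t, p,
    p_adj, sig and large.
    """
    spec.validate()
    needed_pooled = [c for c in spec.contrasts if "all" in c]
    needed_full = [c for c in spec.contrasts if "all" not in c]
    tables: dict[str, pd.DataFrame] = {}
    for pooled, contrasts in ((False, needed_full), (True, needed_pooled)):
        if not contrasts:
            continue
        fit = fit_gene_models(genes, annotation, spec, pooled=pooled)
        s2_post, d0, _s0 = moderate_variances(fit.s2.to_numpy(), fit.df_residual)
        df_total = fit.df_residual + d0
        for contrast in contrasts:
            tables["_".join(contrast)] = _contrast_table(
                fit, contrast, s2_post, df_total, spec
            )
    return tables
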