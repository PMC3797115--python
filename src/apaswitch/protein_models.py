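"""Linear models of protein log fold-change with miRNA usage-score covariates.

The base model regresses per-gene protein log fold-change on the gene's
mRNA log fold-change:

    logFC_prot = b0 + b * logFC_mRNA + e

The slope b is the range-compression coefficient: if absolute protein
quantity scales as P = c * mRNA^b (translational efficiency decaying with
mRNA abundance in log-log scale), then b is exactly the slope of the
log-fold-change regression, so b < 1 is expected and b itself is
interpretable.  miRNA-augmented models add usage-score columns

    logFC_prot = b0 + b * logFC_mRNA - sum_i gamma_i * score_i + e

which is the log-scale image of a per-target-site exponential decay of the
message; gamma_i > 0 means repression by miRNA i where its target isoforms
gain usage.

Model selection: univariate models for every miRNA first, then
combinations of 2..max_size miRNAs restricted to the univariate
FDR-significant set (exhaustive) or grown greedily, ranked by BIC computed
from the Gaussian log-likelihood with the error variance counted as a
parameter:

    BIC = n*log(2*pi*RSS/n) + n + (p + 1) * log(n)

with p regression coefficients including the intercept.  A permutation
bootstrap guards against chance covariates: each miRNA's scores are
shuffled across genes, the model refit, and the fraction of permutations
the true model's R^2 beats is the miRNA's win fraction; explained
variances of high- vs low-win miRNAs are compared by Kruskal-Wallis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_RSS_FLOOR = 1e-300  # keeps the log-likelihood finite on exact fits


@dataclass
class ModelFit:
    """An OLS fit of protein logFC on mRNA logFC plus optional miRNA scores."""

    predictors: list[str]
    coefficients: dict[str, float]
    coef_p: dict[str, float]
    r_squared: float
    bic: float
    n_genes: int
    coef_se: dict[str, float] = field(default_factory=dict)
    residuals: pd.Series = field(repr=False, default=None)
    fitted: pd.Series = field(repr=False, default=None)


@dataclass
class BootstrapResult:
    """Permutation outcome for one miRNA covariate."""

    mirna_id: str
    true_r2: float
    win_fraction: float
    n_permutations: int


def _gaussian_bic(rss: float, n: int, n_coef: int) -> float:
    """BIC with MLE error variance and (n_coef + 1) * log(n) penalty."""
    rss = max(rss, _RSS_FLOOR)
    loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return float(-2.0 * loglik + (n_coef + 1) * np.log(n))


def _fit_ols(y: pd.Series, X: pd.DataFrame) -> ModelFit:
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, Xc).fit()
    rss = float(res.ssr)
    return ModelFit(
        predictors=[c for c in X.columns],
        coefficients={k: float(v) for k, v in res.params.items()},
        coef_p={k: float(v) for k, v in res.pvalues.items()},
        r_squared=float(res.rsquared),
        bic=_gaussian_bic(rss, int(res.nobs), Xc.shape[1]),
        n_genes=int(res.nobs),
        coef_se={k: float(v) for k, v in res.bse.items()},
        residuals=pd.Series(res.resid, index=y.index),
        fitted=pd.Series(res.fittedvalues, index=y.index),
    )


def fit_base(logfc_prot: pd.Series, logfc_mrna: pd.Series,
             min_rows: int = 10) -> ModelFit:
    """OLS of protein logFC on intercept + mRNA logFC.

    Rows are aligned on the shared index; incomplete rows are dropped.
    Residuals are retained for the residual report.
    """
    df = pd.DataFrame({"logfc_prot": logfc_prot, "logfc_mrna": logfc_mrna}).dropna()
    if len(df) < min_rows:
        raise ValueError(f"fit_base needs >= {min_rows} complete gene rows, got {len(df)}")
    if df["logfc_mrna"].nunique() == 1:
        raise ValueError("constant predictor: logfc_mrna has no variance")
    return _fit_ols(df["logfc_prot"], df[["logfc_mrna"]])


def fit_with_mirnas(logfc_prot: pd.Series, logfc_mrna: pd.Series,
                    scores: pd.DataFrame, mirna_subset,
                    min_rows: int = 10, max_size: int = 5) -> ModelFit:
    """OLS with intercept + mRNA logFC + the selected miRNA score columns.

    Preconditions: 1..max_size miRNAs, each score column with variance on
    the fitted rows, no collinear score-column pair (the offending pair is
    named).
    """
    mirna_subset = list(mirna_subset)
    if not 1 <= len(mirna_subset) <= max_size:
        raise ValueError(f"mirna_subset size must be in 1..{max_size}")
    X = scores[mirna_subset].copy()
    X.insert(0, "logfc_mrna", logfc_mrna)
    df = pd.concat([logfc_prot.rename("logfc_prot"), X], axis=1).dropna()
    if len(df) < min_rows:
        raise ValueError(f"fit_with_mirnas needs >= {min_rows} complete rows, got {len(df)}")
    for m in mirna_subset:
        if df[m].nunique() == 1:
            raise ValueError(f"zero-variance score column: {m}")
    if len(mirna_subset) > 1:
        corr = df[mirna_subset].corr().to_numpy()
        for i, j in combinations(range(len(mirna_subset)), 2):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise ValueError("collinear score columns: "
                                 f"{mirna_subset[i]} ~ {mirna_subset[j]}")
    return _fit_ols(df["logfc_prot"], df.drop(columns="logfc_prot"))


# ---------------------------------------------------------------------------
# Fast projection path (used by the combination search and the bootstrap)
# ---------------------------------------------------------------------------

def _base_projection(y: np.ndarray, m: np.ndarray):
    """QR residualisation against [1, mRNA logFC]; returns (res_y, rss_base, tss, Q)."""
    n = y.size
    X = np.column_stack([np.ones(n), m])
    Q, _ = np.linalg.qr(X)
    res_y = y - Q @ (Q.T @ y)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss_base = float(res_y @ res_y)
    return res_y, rss_base, tss, Q

def _r2_with_columns(res_y, rss_base, tss, Q, S: np.ndarray) -> np.ndarray:
    """R^2 of base + each column of S, via partial correlation with res_y."""
    res_S = S - Q @ (Q.T @ S)
    num = res_y @ res_S
    den = np.sqrt(np.maximum(np.sum(res_S * res_S, axis=0) * rss_base, 1e-300))
    c2 = np.clip(num / den, -1.0, 1.0) ** 2
    rss_full = rss_base * (1.0 - c2)
    return 1.0 - rss_full / tss


def _fast_fit(y: np.ndarray, X: np.ndarray):
    """Closed-form OLS of y on X (intercept prepended).

    Returns (r_squared, bic, pvalues) with the same conventions as the
    statsmodels path: t-based two-sided p with n - p residual df, and BIC
    counting the error variance as a parameter.
    """
    n = y.size
    Xc = np.column_stack([np.ones(n), X])
    p = Xc.shape[1]
    XtX = Xc.T @ Xc
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None
    beta = XtX_inv @ (Xc.T @ y)
    resid = y - Xc @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - p
    if dof <= 0:
        return None
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return r2, _gaussian_bic(rss, n, p), pvals


# ---------------------------------------------------------------------------
# Model search
# ---------------------------------------------------------------------------

def search_models(logfc_prot: pd.Series, logfc_mrna: pd.Series,
                  scores: pd.DataFrame,
                  strategy: str = "exhaustive_within_significant",
                  max_size: int = 5, fdr: float = 0.05,
                  max_candidates: int = 15,
                  min_rows: int = 10) -> pd.DataFrame:
    """Rank miRNA-augmented models by BIC.

    Univariate models are fit for every miRNA with score variance on the
    complete rows.  The combination search (2..max_size covariates) is then
    restricted to the univariate-FDR-significant miRNAs, capped at the
    ``max_candidates`` smallest q-values, either exhaustively or greedily
    forward by BIC.  Returns a DataFrame sorted by ascending BIC with one
    row per model (the base model included).
    """
    from .apa_trend import fdr_adjust

    if strategy not in ("exhaustive_within_significant", "greedy_forward"):
        raise ValueError(f"unknown strategy {strategy!r}")
    df = pd.concat([logfc_prot.rename("logfc_prot"),
                    logfc_mrna.rename("logfc_mrna"), scores], axis=1).dropna()
    if len(df) < min_rows:
        raise ValueError(f"search_models needs >= {min_rows} complete rows")
    y = df["logfc_prot"].to_numpy(dtype=float)
    m = df["logfc_mrna"].to_numpy(dtype=float)
    usable = [c for c in scores.columns if df[c].nunique() > 1]
    cols = {c: df[c].to_numpy(dtype=float) for c in usable}
    base = fit_base(df["logfc_prot"], df["logfc_mrna"], min_rows=min_rows)

    rows = [{"predictors": "logfc_mrna", "n_mirnas": 0,
             "r_squared": base.r_squared, "bic": base.bic,
             "min_coef_p": base.coef_p["logfc_mrna"]}]

    def scan(combo: tuple[str, ...]):
        """Fast OLS on intercept + mRNA logFC + the combo's score columns."""
        X = np.column_stack([m] + [cols[c] for c in combo])
        out = _fast_fit(y, X)
        if out is None:
            return None
        r2, bic, pvals = out
        # pvals: [intercept, logfc_mrna, *combo]
        return {"predictors": "logfc_mrna+" + "+".join(combo),
                "n_mirnas": len(combo), "r_squared": r2, "bic": bic,
                "min_coef_p": float(pvals[2:].min())}

    uni_p = {}
    for mi in usable:
        row = scan((mi,))
        if row is None:
            continue
        rows.append(row)
        uni_p[mi] = row["min_coef_p"]
    uni_p = pd.Series(uni_p)
    uni_q = pd.Series(fdr_adjust(uni_p.to_numpy()), index=uni_p.index)

    significant = uni_q[uni_q < fdr].sort_values(kind="mergesort").index.tolist()
    significant = significant[:max_candidates]
    if not significant:
        logger.warning("search_models: no univariate-significant miRNA at "
                       "FDR %g; returning univariate ranking only", fdr)
    elif strategy == "exhaustive_within_significant":
        for k in range(2, min(max_size, len(significant)) + 1):
            for combo in combinations(significant, k):
                row = scan(combo)
                if row is not None:
                    rows.append(row)
    else:  # greedy_forward
        chosen: list[str] = []
        best_bic = base.bic
        while len(chosen) < max_size:
            best_next = None
            for c in significant:
                if c in chosen:
                    continue
                row = scan(tuple(chosen + [c]))
                if row is None:
                    continue
                if row["bic"] < best_bic and (best_next is None
                                              or row["bic"] < best_next[1]["bic"]):
                    best_next = (c, row)
            if best_next is None:
                break
            chosen.append(best_next[0])
            best_bic = best_next[1]["bic"]
            rows.append(best_next[1])
    out = pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(drop=True)
    out.attrs["univariate_q"] = uni_q
    out.attrs["significant"] = significant
    return out


# ---------------------------------------------------------------------------
# Permutation bootstrap
# ---------------------------------------------------------------------------

def bootstrap_mirna(logfc_prot: pd.Series, logfc_mrna: pd.Series,
                    scores: pd.DataFrame, n_perm: int = 1000,
                    seed: int = 0, win_threshold: float = 0.95,
                    min_rows: int = 10) -> tuple[pd.DataFrame, float]:
    """Permutation bootstrap of each miRNA's explained variance.

    For each miRNA the score column is shuffled across genes ``n_perm``
    times and the univariate-augmented model refit; ``win_fraction`` is the
    fraction of permutations the unshuffled model's R^2 strictly exceeds.
    The permutation preserves the multiset of score values exactly.

    Returns the per-miRNA table and the Kruskal-Wallis p-value comparing
    true R^2 between miRNAs with win fraction >= ``win_threshold`` and the
    rest (NaN if either group is empty).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    df = pd.concat([logfc_prot.rename("logfc_prot"),
                    logfc_mrna.rename("logfc_mrna"), scores], axis=1).dropna()
    if len(df) < min_rows:
        raise ValueError(f"bootstrap_mirna needs >= {min_rows} complete rows")
    rng = np.random.default_rng(seed)
    y = df["logfc_prot"].to_numpy(dtype=float)
    m = df["logfc_mrna"].to_numpy(dtype=float)
    res_y, rss_base, tss, Q = _base_projection(y, m)
    results = []
    for mi in scores.columns:
        s = df[mi].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            continue
        true_r2 = float(_r2_with_columns(res_y, rss_base, tss, Q, s[:, None])[0])
        perm = np.empty((s.size, n_perm))
        for j in range(n_perm):
            perm[:, j] = rng.permutation(s)
        perm_r2 = _r2_with_columns(res_y, rss_base, tss, Q, perm)
        win = float(np.mean(true_r2 > perm_r2))
        results.append(BootstrapResult(mi, true_r2, win, n_perm))
    boot = pd.DataFrame([vars(b) for b in results])
    high = boot.loc[boot["win_fraction"] >= win_threshold, "true_r2"]
    low = boot.loc[boot["win_fraction"] < win_threshold, "true_r2"]
    if len(high) and len(low):
        kw_p = float(stats.kruskal(high, low).pvalue)
    else:
        kw_p = float("nan")
    boot.attrs["kruskal_p"] = kw_p
    boot.attrs["win_threshold"] = win_threshold
    boot.attrs["seed"] = seed
    return boot, kw_p


def residual_report(fit: ModelFit, top_k: int | None = None) -> pd.DataFrame:
    """Genes ranked by absolute base-model residual (observed - predicted).

    Negative residuals are proteins suppressed below the mRNA-based
    prediction (candidate post-transcriptional repression); positive the
    converse.
    """
    df = pd.DataFrame({"residual": fit.residuals, "fitted": fit.fitted})
    df["abs_residual"] = df["residual"].abs()
    df = df.sort_values("abs_residual", ascending=False)
    if top_k is not None:
        df = df.head(top_k)
    return df.drop(columns="abs_residual")
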