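"""Statistical layer: binomial logit GLMs with standardized slopes,
ordinary least squares for the CpG transition/transversion ratio kappa,
Spearman correlation panels, the CpG-specific (residual) rate, and the
X-vs-autosome one-way ANOVA.

Substitution-rate responses are (events, sites) binomial pairs modeled
with a logit link; covariates are Z-transformed (mean 0, sample sd 1) so
slopes are standardized and comparable across covariates.  Per-covariate
p-values are two-sided Wald tests, reported as -log10(p) capped at 15.70
(the double-precision floor near 2e-16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

NEG_LOG10_P_CAP = 15.70

#: canonical covariate order for the regression tables
COVARIATES = (
    "noncpg_divergence",
    "methylation",
    "gc_content",
    "expression",
    "recomb_female",
    "recomb_male",
)


class StatsError(ValueError):
    pass


def ztransform(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each column to mean 0, sample (n-1) sd 1.

    Returns the transformed frame and a record of means/sds for inverse
    mapping.  A zero-sd column raises, naming the column.
    """
    means = df.mean()
    sds = df.std(ddof=1)
    bad = sds[(sds == 0) | sds.isna()].index.tolist()
    if bad:
        raise StatsError(f"zero-variance column(s): {bad}")
    z = (df - means) / sds
    record = pd.DataFrame({"mean": means, "sd": sds})
    return z, record


def _neg_log10_p(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        v = -np.log10(np.maximum(p, 0.0))
    return np.minimum(v, NEG_LOG10_P_CAP)


@dataclass
class RegressionResult:
    """Standardized-slope regression summary (binomial GLM or OLS)."""

    family: str
    covariates: list[str]
    standardized_slopes: dict[str, float]
    neg_log10_p: dict[str, float]
    p_values: dict[str, float]
    intercept: float
    null_deviance: float
    residual_deviance: float
    aic: float
    vif: dict[str, float]
    n: int
    r_squared: float = math.nan
    converged: bool = True
    separation: bool = False
    fitted: np.ndarray | None = None
    transform: pd.DataFrame | None = None

    @property
    def explained_deviance(self) -> float:
        return self.null_deviance - self.residual_deviance

    @property
    def pct_explained_deviance(self) -> float:
        if self.null_deviance == 0:
            return math.nan
        return 100.0 * self.explained_deviance / self.null_deviance

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "term": c,
                "estimate": self.standardized_slopes[c],
                "neg_log10_p": self.neg_log10_p[c],
            }
            for c in self.covariates
        ]
        df = pd.DataFrame(rows)
        df.attrs.update(
            explained_deviance=self.explained_deviance,
            residual_deviance=self.residual_deviance,
            pct_explained_deviance=self.pct_explained_deviance,
            aic=self.aic,
            n=self.n,
            r_squared=self.r_squared,
        )
        return df


def _vif(z: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors from auxiliary OLS of each covariate on
    the others; 1.0 for a single covariate."""
    out = {}
    cols = list(z.columns)
    for c in cols:
        others = [o for o in cols if o != c]
        if not others:
            out[c] = 1.0
            continue
        x = sm.add_constant(z[others].to_numpy())
        r2 = sm.OLS(z[c].to_numpy(), x).fit().rsquared
        out[c] = float(1.0 / max(1.0 - r2, 1e-12))
    return out


def complete_cases(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Listwise deletion of rows with any missing value in ``columns``."""
    return df.dropna(subset=[c for c in columns if c in df.columns])


def fit_glm(
    events: np.ndarray,
    sites: np.ndarray,
    covariates: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> RegressionResult:
    """Binomial logit GLM of (events, sites) on Z-scored covariates.

    Fitting is iteratively reweighted least squares (IRLS) to relative
    deviance change < 1e-10.  Slopes are on the Z scale; p-values are
    two-sided Wald.  Quasi-separation is flagged, not silently accepted.
    """
    names = list(covariate_names) if covariate_names is not None else list(covariates.columns)
    events = np.asarray(events, float)
    sites = np.asarray(sites, float)
    if events.shape != sites.shape or len(events) != len(covariates):
        raise StatsError("events/sites/covariates length mismatch")
    if (sites < 1).any():
        raise StatsError("binomial response requires sites >= 1 for every row")
    if (events > sites).any() or (events < 0).any():
        raise StatsError("events must lie in [0, sites]")
    if names:
        z, record = ztransform(covariates[names])
        x = sm.add_constant(z.to_numpy())
    else:  # intercept-only null model
        z, record = pd.DataFrame(index=covariates.index), None
        x = np.ones((len(events), 1))
    endog = np.column_stack([events, sites - events])
    model = sm.GLM(endog, x, family=sm.families.Binomial())
    res = model.fit(maxiter=200, tol=1e-10)
    params = np.asarray(res.params)
    pvals = np.asarray(res.pvalues)
    separation = bool(np.abs(params[1:]).max(initial=0.0) > 25.0)
    return RegressionResult(
        family="binomial-logit",
        covariates=names,
        standardized_slopes=dict(zip(names, params[1:])),
        neg_log10_p=dict(zip(names, _neg_log10_p(pvals[1:]))),
        p_values=dict(zip(names, pvals[1:])),
        intercept=float(params[0]),
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        aic=float(res.aic),
        vif=_vif(z) if names else {},
        n=len(events),
        converged=bool(getattr(res, "converged", True)),
        separation=separation,
        fitted=np.asarray(res.predict(x)),
        transform=record,
    )


def fit_kappa_ols(
    kappa: np.ndarray, covariates: pd.DataFrame, covariate_names: list[str] | None = None
) -> RegressionResult:
    """OLS of the raw CpG transition/transversion ratio on Z-scored
    covariates.  Callers must already have excluded introns with zero
    transversion rate (kappa undefined there)."""
    names = covariate_names or list(covariates.columns)
    y = np.asarray(kappa, float)
    if np.isnan(y).any():
        raise StatsError("kappa contains NaN; exclude undefined rows first")
    z, record = ztransform(covariates[names])
    x = sm.add_constant(z.to_numpy())
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise StatsError("rank-deficient design")
    res = sm.OLS(y, x).fit()
    params = np.asarray(res.params)
    pvals = np.asarray(res.pvalues)
    rss = float(res.ssr)
    tss = float(res.centered_tss)
    return RegressionResult(
        family="gaussian-identity",
        covariates=names,
        standardized_slopes=dict(zip(names, params[1:])),
        neg_log10_p=dict(zip(names, _neg_log10_p(pvals[1:]))),
        p_values=dict(zip(names, pvals[1:])),
        intercept=float(params[0]),
        null_deviance=tss,
        residual_deviance=rss,
        aic=float(res.aic),
        vif=_vif(z),
        n=len(y),
        r_squared=float(res.rsquared),
        fitted=np.asarray(res.fittedvalues),
        transform=record,
    )


def spearman_panel(
    df: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    dataset_column: str = "dataset",
) -> pd.DataFrame:
    """Spearman rank correlations (average ranks for ties) per dataset
    class for the standard panels: CpG o/e vs methylation, CpG o/e vs CpG
    transition rate, CpG transition rate vs methylation."""
    if pairs is None:
        pairs = [
            ("cpg_oe", "methylation"),
            ("cpg_oe", "cpg_ts_rate"),
            ("cpg_ts_rate", "methylation"),
        ]
    rows = []
    groups = [("all", df)]
    if dataset_column in df.columns:
        groups += [(k, g) for k, g in df.groupby(dataset_column)]
    for label, g in groups:
        for x, y in pairs:
            sub = g[[x, y]].dropna()
            if len(sub) < 10:
                rows.append({"dataset": label, "x": x, "y": y, "r_s": math.nan, "n": len(sub)})
                continue
            if sub[x].nunique() < 2 or sub[y].nunique() < 2:
                rows.append({"dataset": label, "x": x, "y": y, "r_s": math.nan, "n": len(sub)})
                continue
            r, _ = sps.spearmanr(sub[x], sub[y])
            rows.append({"dataset": label, "x": x, "y": y, "r_s": float(r), "n": len(sub)})
    return pd.DataFrame(rows)


def cpg_specific_rate(
    events: np.ndarray, sites: np.ndarray, covariates: pd.DataFrame
) -> tuple[np.ndarray, RegressionResult]:
    """Residual CpG transition rate after the five-covariate correction.

    Response residuals of the binomial logit GLM: observed rate minus
    fitted rate, per intron."""
    res = fit_glm(events, sites, covariates)
    observed = np.asarray(events, float) / np.asarray(sites, float)
    residuals = observed - res.fitted
    return residuals, res


def anova_by_chromosome(
    values: np.ndarray, chrom_labels: np.ndarray, x_label: str = "chrX"
) -> pd.DataFrame:
    """One-way ANOVA with the contrast matrix based on the X chromosome.

    The intercept is the X-chromosome mean; each autosome coefficient is
    its difference from X, with two-sided p-values.  Output rows:
    Intercept, then one row per autosome.
    """
    values = np.asarray(values, float)
    chrom_labels = np.asarray(chrom_labels)
    keep = ~np.isnan(values)
    values, chrom_labels = values[keep], chrom_labels[keep]
    levels = sorted(set(chrom_labels))
    if x_label not in levels:
        raise StatsError(f"no {x_label} group present")
    autosomes = [c for c in levels if c != x_label]
    if not autosomes:
        raise StatsError("need at least one autosome group")
    x = np.zeros((len(values), 1 + len(autosomes)))
    x[:, 0] = 1.0
    for j, c in enumerate(autosomes):
        x[:, 1 + j] = chrom_labels == c
    res = sm.OLS(values, x).fit()
    rows = [{"level": "Intercept", "estimate": float(res.params[0]), "p_value": float(res.pvalues[0])}]
    for j, c in enumerate(autosomes):
        rows.append(
            {"level": c, "estimate": float(res.params[1 + j]), "p_value": float(res.pvalues[1 + j])}
        )
    return pd.DataFrame(rows)


#: count columns summed during gene-level concatenation
_COUNT_COLS = (
    "n_cpg_sites",
    "n_cpg_ts",
    "n_cpg_tv",
    "n_cpg_ts_coding",
    "n_cpg_ts_noncoding",
    "n_cpg_double",
    "n_cph_sites",
    "n_cph_ts",
    "n_noncpg_sites",
    "n_sites",
)


def concatenate_by_gene(df: pd.DataFrame) -> pd.DataFrame:
    """Concatenate all introns of each gene into one data point.

    Event and site counts are summed; rates are recomputed from the summed
    counts.  Covariates become site-weighted means (methylation weighted
    by ancestral CpG-site counts); chromosome and dataset labels are taken
    from the gene's first intron.
    """
    if "gene_id" not in df.columns:
        raise StatsError("gene_id column required")
    out_rows = []
    for gene_id, g in df.groupby("gene_id", sort=True):
        row = {"gene_id": gene_id, "n_introns": len(g)}
        for c in _COUNT_COLS:
            if c in g.columns:
                row[c] = g[c].sum()
        w_sites = g["n_sites"].to_numpy(float) if "n_sites" in g.columns else np.ones(len(g))
        w_cpg = g["n_cpg_sites"].to_numpy(float) if "n_cpg_sites" in g.columns else w_sites

        def wmean(col, w):
            v = g[col].to_numpy(float)
            ok = ~np.isnan(v) & (w > 0)
            return float((v[ok] * w[ok]).sum() / w[ok].sum()) if w[ok].sum() > 0 else math.nan

        for col in ("gc_content", "cpg_oe", "expression", "recomb_female", "recomb_male"):
            if col in g.columns:
                row[col] = wmean(col, w_sites)
        if "methylation" in g.columns:
            row["methylation"] = wmean("methylation", w_cpg)
        if "noncpg_divergence" in g.columns and "n_noncpg_sites" in g.columns:
            w = g["n_noncpg_sites"].to_numpy(float)
            row["noncpg_divergence"] = wmean("noncpg_divergence", w)
        for col in ("chrom", "dataset"):
            if col in g.columns:
                row[col] = g[col].iloc[0]
        if row.get("n_cpg_sites", 0) > 0:
            row["cpg_ts_rate"] = row["n_cpg_ts"] / row["n_cpg_sites"]
            row["cpg_tv_rate"] = row["n_cpg_tv"] / row["n_cpg_sites"]
            row["kappa"] = (
                row["cpg_ts_rate"] / row["cpg_tv_rate"] if row["n_cpg_tv"] > 0 else math.nan
            )
        if row.get("n_cph_sites", 0) > 0:
            row["cph_ts_rate"] = row["n_cph_ts"] / row["n_cph_sites"]
        out_rows.append(row)
    return pd.DataFrame(out_rows)
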