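"""Cell-composition and clinical-covariate statistics.

Implements the composition-shift statistics used to quantify border-
associated macrophage (BAM) decline in Alzheimer's disease:

* per-cluster condition enrichment (naive fraction-of-cluster scores,
  normalised so their mean over clusters is 1);
* the BAM2:BAM1 exponential enrichment score
  ``E = exp((n_CD206 - n_MHCII) / N)``;
* the patient capture-quality filter (>= 0.1% of a patient's cells must
  carry a target label);
* module-score signature ratios for CD206-hi vs MHC-II-hi annotation;
* Hampel-filter flagging of per-cluster GWAS-gene expression deltas;
* ordinary least squares models of per-patient BAM frequency against the
  fixed clinical covariate set (sex, Braak, PMI, CERAD, education, APOE
  E2/E4 allele counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "cluster_enrichment",
    "bam_ratio_score",
    "filter_patients",
    "signature_ratio",
    "gwas_delta_flags",
    "clinical_model",
    "ModelFit",
    "CLINICAL_COVARIATES",
]

CLINICAL_COVARIATES = (
    "sex", "braak", "pmi", "cerad", "education", "apoe_e2", "apoe_e4",
)

_MAD_SCALE = 1.4826  # makes the MAD a consistent SD estimate under normality


def cluster_enrichment(
    cells: pd.DataFrame, condition_of_interest: str = "AD"
) -> pd.DataFrame:
    """Per-cluster condition enrichment scores.

    naive score = (# cells of the condition in the cluster) / (cluster size);
    normalised score = naive score / mean(naive scores over clusters).

    Returns a frame indexed by cluster with columns ``n_cells``,
    ``n_condition_cells``, ``naive_score``, ``normalized_score``.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    grouped = cells.groupby("cluster", observed=True)
    n_cells = grouped.size()
    n_cond = (
        cells[cells["condition"] == condition_of_interest]
        .groupby("cluster", observed=True)
        .size()
        .reindex(n_cells.index, fill_value=0)
    )
    naive = n_cond / n_cells
    mean_naive = naive.mean()
    if mean_naive == 0:
        raise ValueError(
            f"no cells with condition {condition_of_interest!r} in any cluster; "
            "normalisation undefined"
        )
    return pd.DataFrame(
        {
            "n_cells": n_cells,
            "n_condition_cells": n_cond,
            "naive_score": naive,
            "normalized_score": naive / mean_naive,
        }
    )


def bam_ratio_score(n_cd206: int, n_mhcii: int, n_total: int) -> float:
    """BAM2:BAM1 enrichment score E = exp((n_CD206 - n_MHCII) / N).

    ``n_total`` is the patient's total cell count (all cells, not only
    macrophages). Values above 1 indicate CD206-hi (BAM2) excess.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if min(n_cd206, n_mhcii) < 0 or max(n_cd206, n_mhcii) > n_total:
        raise ValueError("counts must satisfy 0 <= n <= n_total")
    return float(np.exp((n_cd206 - n_mhcii) / n_total))


def filter_patients(
    cells: pd.DataFrame,
    target_labels,
    min_fraction: float = 0.001,
) -> pd.DataFrame:
    """Drop patients whose fraction of target-labelled cells is below threshold.

    The boundary is inclusive: a patient at exactly ``min_fraction`` is
    retained. Rows of retained patients are returned unchanged.
    """
    target_labels = set(target_labels)
    if not target_labels:
        raise ValueError("target label set must be nonempty")
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must lie in (0, 1)")
    per_patient = cells.groupby("patient_id", observed=True)["cluster"].agg(
        lambda s: s.isin(target_labels).mean()
    )
    keep = per_patient.index[per_patient >= min_fraction]
    return cells[cells["patient_id"].isin(keep)].copy()


def _module_score(
    expr: pd.DataFrame, genes: list[str], seed: int
) -> np.ndarray:
    """Mean expression of a gene set minus a size-matched random background.

    A deliberately simple module score: the background is a random draw of
    the same number of genes from outside the set, not expression-bin
    matched controls. The draw is keyed on the set contents, so identical
    gene sets always receive identical backgrounds.
    """
    import zlib

    key = zlib.crc32("\x1f".join(sorted(genes)).encode())
    rng = np.random.default_rng([seed, key])
    pool = expr.index.difference(genes)
    k = min(len(genes), len(pool))
    background = rng.choice(pool.to_numpy(), size=k, replace=False) if k else []
    fg = expr.loc[genes].mean(axis=0).to_numpy()
    bg = expr.loc[background].mean(axis=0).to_numpy() if k else 0.0
    return fg - bg


def signature_ratio(
    expr: pd.DataFrame,
    clusters: pd.Series,
    set_a: list[str],
    set_b: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster exponentiated signature-score ratio and assignment.

    ``expr`` is genes x cells; ``clusters`` maps cell -> cluster label.
    Per cell, each set's module score is computed, exponentiated, and the
    ratio exp(score_a)/exp(score_b) is averaged within clusters. A cluster
    is called ``set_a-like`` when the ratio exceeds 1, ``set_b-like`` when
    below, ``tie`` at exactly 1.
    """
    if not set_a or not set_b:
        raise ValueError("gene sets must be nonempty")
    missing = [g for g in [*set_a, *set_b] if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression index: {missing}")
    score_a = _module_score(expr, list(set_a), seed)
    score_b = _module_score(expr, list(set_b), seed)
    per_cell = np.exp(score_a - score_b)
    df = pd.DataFrame({"ratio": per_cell, "cluster": clusters.to_numpy()})
    ratio = df.groupby("cluster", observed=True)["ratio"].mean()
    assignment = pd.Series(
        np.where(ratio > 1, "set_a-like", np.where(ratio < 1, "set_b-like", "tie")),
        index=ratio.index,
        name="assignment",
    )
    return pd.DataFrame({"ratio": ratio, "assignment": assignment})


def gwas_delta_flags(per_cluster_delta: pd.Series, k: float = 3.0) -> pd.Series:
    """Hampel-filter outlier flags on per-cluster expression deltas.

    Thresholds are median +- k * (1.4826 * MAD). Values above the upper
    threshold are flagged ``enriched``, below the lower ``depleted``, else
    ``none``. With MAD = 0, any delta differing from the median is flagged
    by its sign (degenerate-scale rule); if all deltas are equal nothing is
    flagged.
    """
    delta = pd.Series(per_cluster_delta, dtype=float)
    if len(delta) < 3:
        raise ValueError("need at least 3 clusters for a Hampel filter")
    m = delta.median()
    mad = _MAD_SCALE * (delta - m).abs().median()
    if mad == 0:
        flags = np.where(delta > m, "enriched", np.where(delta < m, "depleted", "none"))
    else:
        flags = np.where(
            delta > m + k * mad,
            "enriched",
            np.where(delta < m - k * mad, "depleted", "none"),
        )
    return pd.Series(flags, index=delta.index, name="flag")


@dataclass
class ModelFit:
    """OLS coefficient table plus fit diagnostics, as drawn in a forest plot."""

    terms: pd.DataFrame  # index term; columns estimate, se, p
    n: int
    df_resid: int

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        lo = self.terms["estimate"] - t * self.terms["se"]
        hi = self.terms["estimate"] + t * self.terms["se"]
        return pd.DataFrame({"lower": lo, "upper": hi})


def clinical_model(response: pd.Series, covariates: pd.DataFrame) -> ModelFit:
    """OLS of a per-patient response on the fixed clinical covariate set.

    ``response`` is indexed by patient_id (BAM fraction or the exponential
    BAM2:BAM1 score); ``covariates`` carries one row per patient with the
    columns in :data:`CLINICAL_COVARIATES`. Patients present in both inputs
    are used. A rank-deficient design raises with the collinear terms named.
    """
    import statsmodels.api as sm

    cov = covariates.set_index("patient_id") if "patient_id" in covariates else covariates
    common = response.index.intersection(cov.index)
    y = response.loc[common].astype(float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    X = cov.loc[common, list(CLINICAL_COVARIATES)].astype(float)
    if len(common) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} patients, got {len(common)}"
        )
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_terms(design)
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    fit = sm.OLS(y, design).fit()
    terms = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).rename(index={"const": "intercept"})
    return ModelFit(terms=terms, n=int(fit.nobs), df_resid=int(fit.df_resid))


def _collinear_terms(design: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (the redundant directions)."""
    full_rank = np.linalg.matrix_rank(design.to_numpy())
    out = []
    for col in design.columns:
        reduced = design.drop(columns=col).to_numpy()
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(str(col))
    return out
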