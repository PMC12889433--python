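"""Post-processing of Compass-style metabolic reaction penalties.

The upstream flux-balance step (out of scope here) yields a non-negative
penalty per reaction per sample, where a lower penalty means a greater
capacity to carry flux. This module implements everything downstream of the
penalty matrix:

* random pseudobulking of cells into fixed-size metacells within
  (cell type, condition) strata;
* conversion of penalties to flux estimates: flux = -log(1 + penalty),
  min-fixed (shifted so the global minimum is 0) and per-reaction z-scored;
* per-reaction effect sizes (Cohen's d with pooled SD) with rank-sum
  p-values and Benjamini-Hochberg adjustment;
* subsystem (pathway) summaries: median d over member reactions, with a
  >= 3-reaction minimum and an |median d| > 0.1 enrichment call;
* healthy -> AD transition distances: all cross-condition pairwise
  Euclidean distances per cell type, computed through the Gram-matrix
  expansion ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b, with rank-sum
  comparisons of the distance distributions across cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pseudobulk",
    "penalty_to_flux",
    "FluxMatrix",
    "reaction_effects",
    "cohens_d",
    "subsystem_summarize",
    "transition_distance",
    "pairwise_cross_distances",
    "TransitionDistanceResult",
]


# ---------------------------------------------------------------------------
# pseudobulking
# ---------------------------------------------------------------------------

def pseudobulk(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    group_size: int = 10,
    seed: int = 0,
    agg: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Aggregate cells into random fixed-size metacells within strata.

    ``matrix`` is features x cells; ``annotations`` has one row per cell
    with columns ``sample_id``, ``cell_type``, ``condition``. Cells are
    randomly partitioned into disjoint groups of exactly ``group_size``
    within each (cell type, condition) stratum; leftover cells are dropped.
    The metacell value is the member sum (``agg="mean"`` available; after
    per-reaction z-scoring the two are equivalent).

    Returns (metacell matrix, metacell annotations, membership map
    cell -> metacell id). Strata smaller than ``group_size`` yield zero
    metacells and a warning.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if agg not in ("sum", "mean"):
        raise ValueError("agg must be 'sum' or 'mean'")
    rng = np.random.default_rng(seed)
    cols, meta_rows, membership = [], [], {}
    values = []
    ann = annotations.set_index("sample_id")
    # iterate strata in sorted order for seed-stable output
    strata = sorted(
        ann.groupby(["cell_type", "condition"], observed=True).groups.items(),
        key=lambda kv: (str(kv[0][0]), str(kv[0][1])),
    )
    k = 0
    for (cell_type, condition), members in strata:
        ids = np.array(sorted(members))
        if len(ids) < group_size:
            warnings.warn(
                f"stratum ({cell_type}, {condition}) has {len(ids)} cells "
                f"< group_size {group_size}; zero metacells",
                stacklevel=2,
            )
            continue
        perm = rng.permutation(len(ids))
        n_groups = len(ids) // group_size
        for g in range(n_groups):
            take = ids[perm[g * group_size:(g + 1) * group_size]]
            mc_id = f"MC{k:05d}"
            k += 1
            block = matrix[take].to_numpy()
            v = block.sum(axis=1)
            if agg == "mean":
                v = v / group_size
            values.append(v)
            cols.append(mc_id)
            meta_rows.append((mc_id, cell_type, condition))
            for cid in take:
                membership[cid] = mc_id
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "cell_type", "condition"]
    )
    out = pd.DataFrame(
        np.column_stack(values) if values else np.empty((len(matrix), 0)),
        index=matrix.index,
        columns=cols,
    )
    member = pd.Series(membership, name="metacell")
    return out, meta, member


# ---------------------------------------------------------------------------
# penalty -> flux
# ---------------------------------------------------------------------------

@dataclass
class FluxMatrix:
    """Reactions x samples flux estimates with provenance flags."""

    values: pd.DataFrame
    constant_reactions: pd.Index = field(default_factory=lambda: pd.Index([]))
    provenance: tuple[str, ...] = ("raw",)


def penalty_to_flux(
    penalties: pd.DataFrame, min_fix: bool = True, normalize: bool = True
) -> FluxMatrix:
    """flux = -log(1 + penalty), min-fixed and per-reaction z-scored.

    The min-fix subtracts the global minimum of the raw flux matrix so the
    minimum is 0; per-reaction z-scoring (ddof=0 over samples) then makes
    every non-constant row mean 0, SD 1. Constant rows are set to 0 and
    flagged. Since z-scoring is shift-invariant per reaction, the min-fix
    cannot change the output; it is kept (and switchable) for parity with
    the conventional post-processing order.
    """
    vals = penalties.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("penalties must be non-negative")
    raw = -np.log1p(vals)
    prov = ["raw"]
    if min_fix:
        raw = raw - raw.min()
        prov.append("min-fixed")
    if not normalize:
        return FluxMatrix(
            values=pd.DataFrame(raw, index=penalties.index,
                                columns=penalties.columns),
            provenance=tuple(prov),
        )
    sd = raw.std(axis=1, ddof=0)
    mean = raw.mean(axis=1)
    constant = sd == 0
    z = np.zeros_like(raw)
    nz = ~constant
    z[nz] = (raw[nz] - mean[nz, None]) / sd[nz, None]
    prov.append("z-scored")
    return FluxMatrix(
        values=pd.DataFrame(z, index=penalties.index, columns=penalties.columns),
        constant_reactions=penalties.index[constant],
        provenance=tuple(prov),
    )


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    The pooled SD uses n-1 weights. A zero pooled SD yields signed infinity
    when the means differ and 0.0 when they agree.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def reaction_effects(
    flux: FluxMatrix | pd.DataFrame,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Per-reaction Cohen's d between two sample groups with BH-adjusted p.

    p-values come from a two-sided Wilcoxon rank-sum test per reaction;
    adjustment is Benjamini-Hochberg across all reactions of the comparison.
    Reactions with zero pooled SD and unequal means carry a signed-infinity
    d and are excluded from downstream summaries.
    """
    values = flux.values if isinstance(flux, FluxMatrix) else flux
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = values[group_a].to_numpy(dtype=float)
    B = values[group_b].to_numpy(dtype=float)
    d = np.array([cohens_d(A[i], B[i]) for i in range(len(values))])
    p = stats.ranksums(A, B, axis=1).pvalue
    p_adj = multipletests(p, method="fdr_bh")[1]
    n_inf = int(np.isinf(d).sum())
    if n_inf:
        warnings.warn(
            f"{n_inf} reaction(s) with zero pooled SD and unequal means; "
            "d reported as signed infinity and excluded from summaries",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "cohen_d": d,
            "p": p,
            "p_adj": p_adj,
            "n_a": len(group_a),
            "n_b": len(group_b),
        },
        index=values.index.rename("reaction_id"),
    )


def subsystem_summarize(
    effects: pd.DataFrame,
    subsystem_map: pd.Series,
    min_reactions: int = 3,
    d_threshold: float = 0.1,
    p_adj_threshold: float = 0.1,
) -> pd.DataFrame:
    """Median-d pathway summaries with the core-reaction minimum.

    Only subsystems with at least ``min_reactions`` member reactions (after
    dropping infinite-d sentinels) appear; a subsystem is called enriched
    when |median d| exceeds ``d_threshold``. ``n_significant`` counts member
    reactions at BH-adjusted p below ``p_adj_threshold``.
    """
    unmapped = effects.index.difference(subsystem_map.index)
    if len(unmapped):
        raise KeyError(f"reactions without subsystem: {list(unmapped[:5])}")
    df = effects.copy()
    df["subsystem"] = subsystem_map.reindex(df.index)
    df = df[np.isfinite(df["cohen_d"])]
    rows = []
    n_excluded = 0
    for ss, grp in df.groupby("subsystem", observed=True):
        if len(grp) < min_reactions:
            n_excluded += 1
            continue
        med = float(grp["cohen_d"].median())
        rows.append(
            {
                "subsystem": ss,
                "n_reactions": len(grp),
                "median_d": med,
                "direction": int(np.sign(med)),
                "enriched": abs(med) > d_threshold,
                "n_significant": int((grp["p_adj"] < p_adj_threshold).sum()),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "subsystem", "n_reactions", "median_d",
            "direction", "enriched", "n_significant",
        ],
    ).set_index("subsystem")
    out.attrs["n_excluded_subsystems"] = n_excluded
    return out


# ---------------------------------------------------------------------------
# transition distances
# ---------------------------------------------------------------------------

def pairwise_cross_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All Euclidean distances between columns of two feature matrices.

    Uses the squared expansion ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b;
    negative rounding artifacts are clamped at 0 before the square root.
    ``A`` and ``B`` are features x samples; the result is (samples of A) x
    (samples of B).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    sq = (
        (A**2).sum(axis=0)[:, None]
        + (B**2).sum(axis=0)[None, :]
        - 2.0 * (A.T @ B)
    )
    return np.sqrt(np.clip(sq, 0.0, None))


@dataclass
class TransitionDistanceResult:
    """Healthy->AD pairwise-distance distributions per cell type."""

    distances: dict[str, np.ndarray]
    summary: pd.DataFrame  # per cell type: n_pairs, mean, median, q25, q75
    comparisons: pd.DataFrame  # pairwise rank-sum tests across cell types


def transition_distance(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    cell_types=None,
    condition_a: str = "healthy",
    condition_b: str = "AD",
) -> TransitionDistanceResult:
    """Distribution of cross-condition pairwise distances per cell type.

    For each cell type, every (condition_a sample, condition_b sample) pair
    contributes one Euclidean distance over the feature columns; the
    distributions are summarised and compared across cell types with
    two-sided rank-sum tests, BH-adjusted. Cell types missing either
    condition raise.
    """
    ann = annotations.set_index("sample_id")
    if cell_types is None:
        cell_types = sorted(ann["cell_type"].unique())
    distances: dict[str, np.ndarray] = {}
    rows = []
    for ct in cell_types:
        sub = ann[ann["cell_type"] == ct]
        ids_a = sub.index[sub["condition"] == condition_a]
        ids_b = sub.index[sub["condition"] == condition_b]
        if len(ids_a) == 0 or len(ids_b) == 0:
            raise ValueError(
                f"cell type {ct!r} lacks samples in one condition "
                f"({condition_a}: {len(ids_a)}, {condition_b}: {len(ids_b)})"
            )
        d = pairwise_cross_distances(
            features[ids_a].to_numpy(), features[ids_b].to_numpy()
        ).ravel()
        distances[ct] = d
        q25, med, q75 = np.percentile(d, [25, 50, 75])
        rows.append(
            {
                "cell_type": ct,
                "n_pairs": d.size,
                "mean": d.mean(),
                "median": med,
                "q25": q25,
                "q75": q75,
            }
        )
    summary = pd.DataFrame(rows).set_index("cell_type")
    comp_rows = []
    for i, ct1 in enumerate(cell_types):
        for ct2 in cell_types[i + 1:]:
            stat, p = stats.ranksums(distances[ct1], distances[ct2])
            comp_rows.append({"a": ct1, "b": ct2, "statistic": stat, "p": p})
    comparisons = pd.DataFrame(
        comp_rows, columns=["a", "b", "statistic", "p"]
    )
    if len(comparisons):
        comparisons["p_adj"] = multipletests(comparisons["p"], method="fdr_bh")[1]
    else:
        comparisons["p_adj"] = pd.Series(dtype=float)
    return TransitionDistanceResult(distances, summary, comparisons)
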