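"""Per-replicate cluster proportions and enrichment/depletion calls.

Each biological replicate contributes one composition vector (fractions of
its cells across clusters).  For each contrast (EoE vs control, ESCC vs
control) every cluster is tested with the exact two-sided Mann–Whitney
rank-sum test on per-replicate proportions — the groups are unpaired and of
unequal size, so a signed-rank (paired) test is not applicable — followed by
Benjamini–Hochberg (or Bonferroni) adjustment across clusters within the
contrast.  Direction is the sign of the median difference; a cluster is
enriched/depleted only when its adjusted p falls below alpha.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["cluster_proportions", "compare_abundance", "enrichment_summary"]


def cluster_proportions(
    clusters: np.ndarray, cell_meta: pd.DataFrame
) -> pd.DataFrame:
    """Rows = (replicate, condition); columns = clusters; entries = fractions."""
    for col in ("replicate", "condition"):
        if col not in cell_meta.columns:
            raise ValueError(f"cell_meta must carry a {col!r} column")
        if cell_meta[col].isna().any():
            raise ValueError(f"cells with missing {col!r} label")
    clusters = np.asarray(clusters)
    df = pd.DataFrame(
        {
            "replicate": cell_meta["replicate"].to_numpy(),
            "condition": cell_meta["condition"].to_numpy(),
            "cluster": clusters,
        }
    )
    counts = (
        df.groupby(["replicate", "condition"], sort=True, observed=True)["cluster"]
        .value_counts()
        .unstack(fill_value=0)
        .sort_index(axis=1)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    return props


def _exact_rank_test(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Mann–Whitney p; degenerate all-tied data gives p = 1."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    try:
        return float(mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    except ValueError:  # ties force the normal approximation
        return float(mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def compare_abundance(
    props: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Per-cluster enrichment/depletion calls for ``contrast = (case, reference)``.

    Returns one row per cluster with raw p, adjusted p, and direction
    ('enriched' / 'depleted' / 'ns'), where direction refers to the case group
    relative to the reference.
    """
    case, ref = contrast
    cond = props.index.get_level_values("condition")
    A = props[cond == case]
    B = props[cond == ref]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each contrast group needs at least 2 replicates")
    rows = []
    for cluster in props.columns:
        a = A[cluster].to_numpy(dtype=float)
        b = B[cluster].to_numpy(dtype=float)
        p = _exact_rank_test(a, b)
        med_diff = float(np.median(a) - np.median(b))
        rows.append({"cluster": cluster, "contrast": f"{case} vs {ref}",
                     "median_diff": med_diff, "p": p})
    df = pd.DataFrame(rows)
    method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
    df["p_adj"] = multipletests(df["p"], method=method)[1]
    direction = np.where(
        df["p_adj"] < alpha,
        np.where(df["median_diff"] > 0, "enriched", "depleted"),
        "ns",
    )
    # a significant call with an exactly-zero median difference is ambiguous;
    # fall back to the mean difference sign (ties this fine are rare)
    zero_sig = (df["p_adj"] < alpha) & (df["median_diff"] == 0)
    if zero_sig.any():
        for i in np.flatnonzero(zero_sig):
            cluster = df.loc[i, "cluster"]
            diff = A[cluster].mean() - B[cluster].mean()
            direction[i] = "enriched" if diff > 0 else "depleted"
    df["direction"] = direction
    return df.set_index("cluster")


def enrichment_summary(
    calls: dict[str, pd.DataFrame], strata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Join calls across contrasts; flag clusters significant in exactly one.

    ``calls`` maps a contrast label (e.g. 'EoE') to the output of
    :func:`compare_abundance`; ``strata`` optionally adds the stratum label.
    """
    frames = []
    for label, df in calls.items():
        sub = df[["direction", "p", "p_adj"]].copy()
        sub.columns = [f"{label}_{c}" for c in sub.columns]
        frames.append(sub)
    joined = pd.concat(frames, axis=1)
    sig = pd.DataFrame(
        {label: calls[label]["direction"] != "ns" for label in calls}
    )
    joined["unique"] = sig.sum(axis=1) == 1
    if strata is not None:
        joined.insert(0, "stratum", strata["stratum"].reindex(joined.index))
    return joined
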