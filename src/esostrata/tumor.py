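"""In vivo tumor-burden endpoints: load, incidence, lesion spectrum.

Per-mouse tumor load is tumor number × total tumor area (mm²).  Incidence
(tumor-bearing fraction) between two groups is compared with a two-sided
Fisher exact test computed by full hypergeometric enumeration (tables with
probability ≤ the observed table's are summed).  Group loads and percent
neoplastic epithelium are compared with the unpaired equal-variance Student
t-test.  Lesion-grade spectra are compared with an exact R×C Fisher test by
enumeration of all tables with the observed margins, falling back to a
Monte-Carlo p for large supports.
"""
from __future__ import annotations

from math import comb, lgamma

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

__all__ = [
    "parse_areas",
    "tumor_load",
    "tumor_loads",
    "incidence_test",
    "load_comparison",
    "lesion_spectrum",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
]

LESION_ORDER = ("none", "IEN", "early ESCC", "invasive ESCC")


def parse_areas(areas) -> np.ndarray:
    """Accept a list of areas or a ';'-joined string field."""
    if isinstance(areas, str):
        return np.array([float(a) for a in areas.split(";") if a.strip()]) if areas.strip() else np.array([])
    return np.asarray(list(areas), dtype=float)


def tumor_load(tumor_count: int, tumor_areas, mean_area: bool = False) -> float:
    """count × total area (mm²); with ``mean_area``, count × mean area."""
    areas = parse_areas(tumor_areas)
    if (areas < 0).any():
        raise ValueError("tumor areas must be nonnegative")
    if tumor_count != len(areas):
        raise ValueError(
            f"tumor_count={tumor_count} but {len(areas)} areas recorded"
        )
    if tumor_count == 0:
        return 0.0
    agg = areas.mean() if mean_area else areas.sum()
    return float(tumor_count * agg)


def tumor_loads(table: pd.DataFrame, mean_area: bool = False) -> pd.Series:
    """Per-mouse loads from a tumor-study table."""
    return pd.Series(
        {
            idx: tumor_load(int(row["tumor_count"]), row["tumor_areas"], mean_area)
            for idx, row in table.iterrows()
        },
        name="tumor_load",
    )


# ----------------------------------------------------------------------
def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×2 table by hypergeometric enumeration."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    r1, r2 = t.sum(axis=1)
    c1, _ = t.sum(axis=0)
    n = r1 + r2

    def prob(a: int) -> float:
        return comb(c1, a) * comb(n - c1, r1 - a) / comb(n, r1)

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    p_obs = prob(t[0, 0])
    return float(sum(p for p in (prob(a) for a in range(lo, hi + 1)) if p <= p_obs * (1 + 1e-12)))


def _table_log_prob(t: np.ndarray, lg_margins: float) -> float:
    return lg_margins - sum(lgamma(x + 1) for x in t.ravel())


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    R, C = len(row_sums), len(col_sums)

    def rec(r, remaining_cols, rows):
        if r == R - 1:
            last = np.array(remaining_cols)
            if (last >= 0).all():
                yield rows + [last]
            return
        def fill(c, left, row):
            if c == C - 1:
                if 0 <= left <= remaining_cols[c]:
                    yield row + [left]
                return
            for x in range(0, min(left, remaining_cols[c]) + 1):
                yield from fill(c + 1, left - x, row + [x])
        for row in fill(0, row_sums[r], []):
            new_rem = [rc - x for rc, x in zip(remaining_cols, row)]
            yield from rec(r + 1, new_rem, rows + [np.array(row)])

    yield from rec(0, list(col_sums), [])


def fisher_exact_rxc(
    table: np.ndarray,
    max_tables: int = 1_000_000,
    n_mc: int = 20_000,
    seed: int = 0,
) -> tuple[float, str]:
    """Exact (or Monte-Carlo) two-sided Fisher p for an R×C table.

    Enumerates every table with the observed margins when the support is
    small (probability-mass criterion, as in the 2×2 case); otherwise draws
    ``n_mc`` tables from the margin-conditional null via random permutation
    and reports the add-one Monte-Carlo p.  Returns (p, method).
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    # drop empty rows/cols: they contribute nothing to the support
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or 1 in t.shape:
        return 1.0, "exact"
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    n = t.sum()
    lg_margins = (
        sum(lgamma(x + 1) for x in row_sums)
        + sum(lgamma(x + 1) for x in col_sums)
        - lgamma(n + 1)
    )
    # rough support-size bound: product over rows of compositions
    bound = 1
    for r in row_sums:
        bound *= comb(int(r) + len(col_sums) - 1, len(col_sums) - 1)
        if bound > max_tables:
            break
    lp_obs = _table_log_prob(t, lg_margins)
    if bound <= max_tables:
        total = 0.0
        p = 0.0
        for tab in _enumerate_tables(row_sums, col_sums):
            lp = _table_log_prob(np.array(tab), lg_margins)
            pr = float(np.exp(lp))
            total += pr
            if lp <= lp_obs + 1e-9:
                p += pr
        assert abs(total - 1.0) < 1e-9, "enumeration probabilities must sum to 1"
        return min(p, 1.0), "exact"
    # Monte-Carlo: permute column labels of the n items
    rng = np.random.default_rng(seed)
    rows_of_item = np.repeat(np.arange(len(row_sums)), row_sums)
    cols_of_item = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols_of_item)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows_of_item, perm), 1)
        if _table_log_prob(sim, lg_margins) <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1), "monte-carlo"


# ----------------------------------------------------------------------
def incidence_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> dict:
    """Tumor incidence (percent tumor-bearing) in two groups + Fisher exact p."""
    bearing_a = int((group_a["tumor_count"] > 0).sum())
    bearing_b = int((group_b["tumor_count"] > 0).sum())
    na, nb = len(group_a), len(group_b)
    if na < 1 or nb < 1:
        raise ValueError("each group needs at least one mouse")
    table = np.array([[bearing_a, na - bearing_a], [bearing_b, nb - bearing_b]])
    return {
        "table": table,
        "incidence_a_pct": 100.0 * bearing_a / na,
        "incidence_b_pct": 100.0 * bearing_b / nb,
        "p": fisher_exact_2x2(table),
    }


def load_comparison(values_a, values_b) -> dict:
    """Unpaired equal-variance Student t-test on per-mouse values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two mice")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0}
        raise ValueError("zero variance in both groups with unequal means")
    res = ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def lesion_spectrum(table: pd.DataFrame, groups: list[str] | None = None, seed: int = 0) -> dict:
    """Grade-frequency table across groups + exact/MC Fisher p."""
    sub = table if groups is None else table[table["group"].isin(groups)]
    freq = (
        sub.groupby("group", observed=True)["lesion_grade"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[g for g in LESION_ORDER if g in set(sub["lesion_grade"])],
                 fill_value=0)
    )
    p, method = fisher_exact_rxc(freq.to_numpy(), seed=seed)
    return {"frequencies": freq, "p": p, "method": method}
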