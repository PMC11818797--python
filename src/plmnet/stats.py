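"""Permutation-based group comparison with FDR control, and correlations.

The two-group test statistic is the absolute difference of group means.
Its null distribution is built by randomly reassigning the group labels
(50,000 shuffles by default); when the number of distinct assignments is
no larger than the shuffle budget the test enumerates them exhaustively
instead, giving the exact permutation p-value.

Multiple testing across the six lobe groups is corrected per band by the
Benjamini-Hochberg step-up procedure at q = 0.05.  Associations with
clinical scores use Pearson's r with the t-transform p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .atlas import LOBE_GROUPS

__all__ = [
    "PermutationResult",
    "CorrelationResult",
    "permutation_test",
    "bh_fdr",
    "pearson_correlation",
    "run_group_comparison",
    "run_correlations",
]


@dataclass
class PermutationResult:
    band: str
    lobe: str
    observed_abs_mean_diff: float
    p_raw: float
    p_fdr: float
    n_permutations: int
    seed: int | None
    direction: str  # 'PD_higher' or 'HC_higher'
    n_a: int = 0
    n_b: int = 0


@dataclass
class CorrelationResult:
    band: str
    lobe: str
    variable: str
    r: float
    p_raw: float
    p_fdr: float
    n: int


def permutation_test(values_a, values_b, n_perm: int = 50_000,
                     seed: int | None = None, smooth: bool = True):
    """Two-sided permutation test on |mean(a) - mean(b)|.

    Returns ``(observed, p, n_used, exhaustive)``.  All C(n_a+n_b, n_a)
    relabelings are enumerated when their count does not exceed
    ``n_perm`` (exact p = proportion of assignments with a statistic at
    least as extreme, the observed one included); otherwise ``n_perm``
    random shuffles are drawn and, with ``smooth`` (default), the
    add-one estimate p = (1 + #extreme) / (1 + n_perm) is used so that
    p > 0 is guaranteed.  Deterministic given ``seed``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")

    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = abs(a.mean() - b.mean())
    # Tolerance for ties between surrogate and observed statistics.
    tie_eps = 1e-12 * max(1.0, float(np.abs(pooled).max()))

    n_total = math.comb(n, na)
    if n_total <= n_perm:
        total = pooled.sum()
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (total - sa) / (n - na))
            if stat >= observed - tie_eps:
                count += 1
        return observed, count / n_total, n_total, True

    rng = np.random.default_rng(seed)
    # Vectorized shuffles in blocks to bound memory at large n_perm.
    extreme = 0
    block = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    total = pooled.sum()
    while done < n_perm:
        m = min(block, n_perm - done)
        perm = rng.permuted(np.broadcast_to(np.arange(n), (m, n)).copy(), axis=1)
        sa = pooled[perm[:, :na]].sum(axis=1)
        stat = np.abs(sa / na - (total - sa) / (n - na))
        extreme += int(np.sum(stat >= observed - tie_eps))
        done += m
    if smooth:
        p = (1 + extreme) / (1 + n_perm)
    else:
        p = extreme / n_perm if extreme else 1.0 / (1 + n_perm)
    return observed, p, n_perm, False


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted p-values, rejection flags)`` with the usual
    monotonicity enforcement; a hypothesis is rejected when its adjusted
    p-value is <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def pearson_correlation(x, y):
    """Sample Pearson r with the two-sided t-transform p-value (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input has no defined correlation")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def _subgroup_mask(cohort: pd.DataFrame, subgroup: str | None) -> pd.DataFrame:
    if subgroup is None:
        return cohort
    sex = {"male": "M", "female": "F"}.get(subgroup, subgroup)
    if sex not in ("M", "F"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    return cohort[cohort["sex"] == sex]


def run_group_comparison(lobe_table: pd.DataFrame, cohort: pd.DataFrame,
                         bands=None, n_perm: int = 50_000,
                         seed: int | None = None, q: float = 0.05,
                         subgroup: str | None = None,
                         fdr_family: str = "band") -> pd.DataFrame:
    """Permutation tests of lobe centrality between the PD and HC groups.

    Parameters
    ----------
    lobe_table : DataFrame with columns subject_id, band, lobe, ec_mean.
    cohort : DataFrame with columns subject_id, group (PD/HC), sex.
    bands : bands to test (default: all present in ``lobe_table``).
    fdr_family : 'band' corrects across the 6 lobes within each band
        (default); 'global' corrects across all band x lobe tests.
    subgroup : optional 'male' / 'female' restriction; both groups must
        remain non-empty.

    Returns a DataFrame with one row per (band, lobe): the observed
    absolute mean difference, raw and BH-adjusted p-values, direction of
    the difference, group sizes, and the seed used.
    """
    cohort = _subgroup_mask(cohort, subgroup)
    pd_ids = set(cohort.loc[cohort["group"] == "PD", "subject_id"])
    hc_ids = set(cohort.loc[cohort["group"] == "HC", "subject_id"])
    if not pd_ids or not hc_ids:
        raise ValueError("a group is empty after subgroup filtering")
    if bands is None:
        bands = list(dict.fromkeys(lobe_table["band"]))

    wanted = pd_ids | hc_ids
    have = set(lobe_table["subject_id"])
    missing = sorted(wanted - have)
    if missing:
        raise ValueError(f"lobe table is missing subjects: {missing}")

    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)
    rows = []
    for band in bands:
        sub = lobe_table[lobe_table["band"] == band]
        lobes = [g for g in LOBE_GROUPS if g in set(sub["lobe"])]
        for lobe in lobes:
            cell = sub[sub["lobe"] == lobe].set_index("subject_id")["ec_mean"]
            va = cell.reindex(sorted(pd_ids)).to_numpy()
            vb = cell.reindex(sorted(hc_ids)).to_numpy()
            if np.any(np.isnan(va)) or np.any(np.isnan(vb)):
                raise ValueError(f"missing {band}/{lobe} values for some subjects")
            child = seed_seq.spawn(1)[0]
            test_seed = int(child.generate_state(1)[0] % (2 ** 31))
            obs, p, n_used, _ = permutation_test(va, vb, n_perm=n_perm,
                                                 seed=test_seed)
            rows.append({
                "band": band, "lobe": lobe, "stat": obs, "p_raw": p,
                "direction": "PD_higher" if va.mean() >= vb.mean() else "HC_higher",
                "n_permutations": n_used, "seed": test_seed,
                "n_a": va.size, "n_b": vb.size,
            })
    res = pd.DataFrame(rows)
    res["p_fdr"] = np.nan
    res["significant"] = False
    if fdr_family == "global":
        adj, rej = bh_fdr(res["p_raw"].to_numpy(), q=q)
        res["p_fdr"], res["significant"] = adj, rej
    elif fdr_family == "band":
        for band in res["band"].unique():
            m = res["band"] == band
            adj, rej = bh_fdr(res.loc[m, "p_raw"].to_numpy(), q=q)
            res.loc[m, "p_fdr"] = adj
            res.loc[m, "significant"] = rej
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return res


def run_correlations(lobe_table: pd.DataFrame, cohort: pd.DataFrame,
                     comparison: pd.DataFrame | None = None,
                     variables=("updrs3", "disease_duration"),
                     all_pairs: bool = False, q: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of lobe centrality with clinical scores, PD group only.

    By default only the (band, lobe) cells flagged significant in the
    group ``comparison`` are correlated, mirroring the practice of
    following up group differences; ``all_pairs=True`` correlates every
    cell.  BH correction is applied within each clinical variable across
    the computed cells.
    """
    pd_rows = cohort[cohort["group"] == "PD"]
    if comparison is None and not all_pairs:
        raise ValueError("need a comparison table unless all_pairs=True")
    if all_pairs:
        cells = lobe_table[["band", "lobe"]].drop_duplicates().itertuples(index=False)
    else:
        sig = comparison[comparison["significant"]]
        cells = sig[["band", "lobe"]].drop_duplicates().itertuples(index=False)

    rows = []
    for band, lobe in cells:
        cell = lobe_table[(lobe_table["band"] == band)
                          & (lobe_table["lobe"] == lobe)]
        merged = cell.merge(pd_rows, on="subject_id")
        for var in variables:
            vals = merged[["ec_mean", var]].dropna()
            if len(vals) < 3 or vals[var].std() == 0:
                continue
            r, p = pearson_correlation(vals["ec_mean"], vals[var])
            rows.append({"band": band, "lobe": lobe, "variable": var,
                         "r": r, "p_raw": p, "n": len(vals)})
    res = pd.DataFrame(rows, columns=["band", "lobe", "variable", "r",
                                      "p_raw", "n"])
    res["p_fdr"] = np.nan
    res["significant"] = False
    for var in res["variable"].unique():
        m = res["variable"] == var
        adj, rej = bh_fdr(res.loc[m, "p_raw"].to_numpy(), q=q)
        res.loc[m, "p_fdr"] = adj
        res.loc[m, "significant"] = rej
    return res
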