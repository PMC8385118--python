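"""Group screening and supporting statistics for the feature table.

Covers robust outlier replacement (scaled-MAD rule), per-block two-sample
t-screening of the 50 analysis variables with Benjamini-Hochberg FDR control
within each block's family, hierarchical ordering of variables by their
t-statistic profiles, Spearman / repeated-measures correlation suites, the
quartile grouping of the difficulty-adjustment balance, and the noncentral-t
power computation for two-group designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenResult",
    "mad_replace",
    "group_screen",
    "cluster_variable_order",
    "correlation_suite",
    "quartile_groups",
    "power_sample_size",
]


@dataclass
class ScreenResult:
    table: pd.DataFrame  # columns: variable, block, t, p, p_adj, significant
    variable_order: list[str] = field(default_factory=list)

    def t_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="variable", columns="block", values="t")

    def significant_fraction(self, alpha: float = 0.05) -> pd.Series:
        return self.table.groupby("block", sort=False)["p_adj"].apply(lambda p: float((p < alpha).mean()))


def mad_replace(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace values > 3 scaled MADs from the median by the clean median.

    scaled MAD = 1.4826 * median(|x - median(x)|).  Flagged values are
    replaced (single pass) by the median of the non-flagged values.  With a
    degenerate scaled MAD of zero nothing is replaced and a warning is issued
    (the literal rule would flag every non-median value).
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("mad_replace needs at least 3 finite values")
    med = np.median(x[finite])
    smad = 1.4826 * np.median(np.abs(x[finite] - med))
    if smad == 0:
        warnings.warn("scaled MAD is zero; outlier replacement skipped")
        return x.copy(), np.zeros_like(x, dtype=bool)
    mask = finite & (np.abs(x - med) > 3.0 * smad)
    out = x.copy()
    if mask.any():
        out[mask] = np.median(x[finite & ~mask])
    return out, mask


def _two_sample_t(a: np.ndarray, b: np.ndarray, levene_alpha: float = 0.05) -> tuple[float, float]:
    """Pooled-variance t by default; Welch when Levene's test rejects."""
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("nan"), float("nan")
    _, p_lev = stats.levene(a, b)
    equal_var = not (np.isfinite(p_lev) and p_lev < levene_alpha)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def group_screen(
    features: pd.DataFrame,
    blocks: list[str] | None = None,
    alpha: float = 0.05,
    stress_label: str = "stress",
) -> ScreenResult:
    """Stress-vs-control t-test per variable per block, BH within each block.

    ``features`` is the wide analysis table (participant_id, group, block +
    the 50 analysis columns).  The t statistic is oriented stress - control.
    """
    meta = {"participant_id", "group", "block"}
    variables = [c for c in features.columns if c not in meta]
    if blocks is None:
        blocks = [b for b in features["block"].unique()]
    rows = []
    for block in blocks:
        sub = features[features["block"] == block]
        s = sub[sub["group"] == stress_label]
        c = sub[sub["group"] != stress_label]
        if len(s) < 2 or len(c) < 2:
            raise ValueError(f"block {block}: both groups need >= 2 participants")
        for v in variables:
            t, p = _two_sample_t(s[v].to_numpy(float), c[v].to_numpy(float))
            rows.append({"variable": v, "block": block, "t": t, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for block in blocks:
        m = (table["block"] == block) & np.isfinite(table["p"])
        if m.any():
            table.loc[m, "p_adj"] = multipletests(table.loc[m, "p"], method="fdr_bh")[1]
    table["significant"] = table["p_adj"] < alpha
    tmat = table.pivot(index="variable", columns="block", values="t").fillna(0.0)
    order = cluster_variable_order(tmat.to_numpy(), list(tmat.index))
    return ScreenResult(table=table, variable_order=order)


def cluster_variable_order(t_matrix: np.ndarray, names: list[str] | None = None) -> list:
    """Leaf order of average-linkage Euclidean clustering of the t-profile rows."""
    t_matrix = np.asarray(t_matrix, dtype=float)
    if t_matrix.ndim != 2 or t_matrix.shape[0] < 2:
        raise ValueError("need at least 2 variables (rows) to order")
    z = linkage(t_matrix, method="average", metric="euclidean")
    order = list(leaves_list(z))
    if names is not None:
        return [names[i] for i in order]
    return order


def rm_correlation(df: pd.DataFrame, x: str, y: str, subject: str) -> tuple[float, float]:
    """Repeated-measures correlation: common within-subject association.

    Computed via pingouin's ANCOVA-style construction (subject-mean removal
    with a common slope).  Returns (r, p); (nan, nan) on degenerate input.
    """
    import pingouin as pg

    sub = df[[subject, x, y]].dropna()
    if sub[x].nunique() < 2 or sub[y].nunique() < 2 or sub[subject].nunique() < 2:
        return float("nan"), float("nan")
    try:
        res = pg.rm_corr(data=sub, x=x, y=y, subject=subject)
    except Exception:
        return float("nan"), float("nan")
    return float(res["r"].iloc[0]), float(res["pval"].iloc[0])


def correlation_suite(
    behavior: pd.DataFrame,
    physio: pd.DataFrame,
    subject: str = "participant_id",
    block: str = "block",
) -> dict[str, pd.DataFrame]:
    """Spearman (between-subject, T1-T4 means) and rm-correlation matrices.

    ``behavior`` and ``physio`` are long tables with one row per
    (participant, block) and metric columns.  Spearman correlates participant
    means across blocks; the rm-correlation uses the per-block repeated
    measures.  p-values are BH-adjusted within each correlation modality.
    """
    bvars = [c for c in behavior.columns if c not in (subject, block)]
    pvars = [c for c in physio.columns if c not in (subject, block)]
    merged = behavior.merge(physio, on=[subject, block], how="inner")
    if merged[subject].nunique() < 4:
        raise ValueError("correlation suite needs >= 4 participants")

    means = merged.groupby(subject)[bvars + pvars].mean()
    sp_r = pd.DataFrame(index=bvars, columns=pvars, dtype=float)
    sp_p = pd.DataFrame(index=bvars, columns=pvars, dtype=float)
    rm_r = pd.DataFrame(index=bvars, columns=pvars, dtype=float)
    rm_p = pd.DataFrame(index=bvars, columns=pvars, dtype=float)
    for bv in bvars:
        for pv in pvars:
            if means[bv].nunique() < 2 or means[pv].nunique() < 2:
                r = p = float("nan")
            else:
                r, p = stats.spearmanr(means[bv], means[pv])
            sp_r.loc[bv, pv], sp_p.loc[bv, pv] = r, p
            r, p = rm_correlation(merged, bv, pv, subject)
            rm_r.loc[bv, pv], rm_p.loc[bv, pv] = r, p

    def adjust(pmat: pd.DataFrame) -> pd.DataFrame:
        flat = pmat.to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        return pd.DataFrame(adj.reshape(pmat.shape), index=pmat.index, columns=pmat.columns)

    return {
        "spearman_r": sp_r,
        "spearman_p_adj": adjust(sp_p),
        "rm_r": rm_r,
        "rm_p_adj": adjust(rm_p),
    }


def quartile_groups(balance: np.ndarray) -> np.ndarray:
    """Quartile labels (1-4) of the adjustment balance; ties to the lower quartile."""
    x = np.asarray(balance, dtype=float)
    if len(x) < 4:
        raise ValueError("quartile grouping needs >= 4 participants")
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    labels = 1 + (x > q1).astype(int) + (x > q2).astype(int) + (x > q3).astype(int)
    if np.all(labels == 1) and len(np.unique(x)) == 1:
        warnings.warn("all balance values identical; every participant in quartile 1")
    return labels


def power_sample_size(
    effect_size: float,
    power: float = 0.80,
    alpha: float = 0.05,
    tails: int = 1,
) -> int:
    """Smallest total N (two equal groups) for a two-sample t-test.

    Power is evaluated exactly with the noncentral t distribution:
    ncp = d * sqrt(n/2), df = 2n - 2.  Returns 2n for the smallest per-group
    n achieving the requested power.
    """
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    if power <= alpha:
        raise ValueError("requested power must exceed alpha")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")

    def achieved(n: int) -> float:
        df = 2 * n - 2
        ncp = effect_size * float(np.sqrt(n / 2.0))
        if tails == 1:
            crit = stats.t.ppf(1 - alpha, df)
            return float(1 - stats.nct.cdf(crit, df, ncp))
        crit = stats.t.ppf(1 - alpha / 2, df)
        return float((1 - stats.nct.cdf(crit, df, ncp)) + stats.nct.cdf(-crit, df, ncp))

    n = 2
    while achieved(n) < power:
        n += 1
        if n > 10**6:
            raise RuntimeError("sample size search did not converge")
    return 2 * n
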