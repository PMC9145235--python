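"""Population-level descriptive statistics of the trait table.

Covers the three descriptive analyses run on a phenotyped panel of inbred
lines: per-trait variation summaries (median / min / max and the max/min
fold), Spearman rank correlation with average-linkage hierarchical
clustering of traits (distance 1 - rho), and one-way ANOVA across
subpopulation groups followed by Duncan's multiple range test with
compact letter display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import registry
from .exceptions import ValidationError

SUBGROUPS = ("SS", "NSS", "TST", "Mixed")


def variation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median, minimum, maximum and fold variation (max/min) per trait.

    Traits whose minimum is <= 0 get ``fold = NaN`` and
    ``fold_defined = False`` instead of a misleading ratio.
    """
    if table.shape[1] == 0:
        raise ValidationError("empty trait table")
    rows = []
    for col in table.columns:
        v = table[col].dropna().to_numpy(float)
        if v.size == 0:
            raise ValidationError(f"trait {col!r} has no non-missing values")
        vmin, vmax = float(v.min()), float(v.max())
        defined = vmin > 0
        rows.append(
            {
                "trait": col,
                "median": float(np.median(v)),
                "minimum": vmin,
                "maximum": vmax,
                "fold": vmax / vmin if defined else np.nan,
                "fold_defined": defined,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


@dataclass
class SpearmanClusterResult:
    """Correlation matrix, two-sided p-values, significance, trait groups."""

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # p <= alpha flags
    groups: pd.Series          # trait -> cluster id (1..k)
    alpha: float


def _spearman_matrix(table: pd.DataFrame):
    """Pairwise-complete Spearman rho with t-approximation p-values."""
    cols = list(table.columns)
    rho = table.corr(method="spearman")  # tie-corrected, pairwise complete
    notna = table.notna().to_numpy()
    n_pair = notna.T.astype(int) @ notna.astype(int)
    r = rho.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_pair - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n_pair - 2, 1))
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    pv = pd.DataFrame(p, index=cols, columns=cols)
    return rho, pv


def spearman_cluster(
    table: pd.DataFrame, k: int = 4, alpha: float = 0.05
) -> SpearmanClusterResult:
    """Spearman correlation of traits plus agglomerative trait clustering.

    Distance is 1 - rho with average linkage, cut into ``k`` groups.
    Columns are processed in trait-registry order when they are registry
    traits, otherwise in table order, making tie-breaks deterministic.
    """
    if table.dropna().shape[0] < 3:
        raise ValidationError("need at least 3 complete rows")
    if k > table.shape[1]:
        raise ValidationError("k exceeds the number of traits")
    known = set(registry.trait_names())
    cols = sorted(
        table.columns,
        key=lambda c: (registry.trait_index(c) if c in known else 10_000,
                       list(table.columns).index(c)),
    )
    table = table[cols]
    rho, pv = _spearman_matrix(table)
    d = 1.0 - rho.to_numpy(float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(np.clip(d, 0.0, None), checks=False),
                method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    groups = pd.Series(labels, index=cols, name="group")
    return SpearmanClusterResult(rho, pv, pv <= alpha, groups, alpha)


@dataclass
class DuncanResult:
    """One-way ANOVA F test plus Duncan's multiple-range letter display.

    Groups sharing any letter do not differ at level alpha; letters are
    assigned to contiguous runs of the descending-sorted means.
    """

    f_stat: float
    p_value: float
    alpha: float
    means: pd.Series     # group -> mean, descending
    letters: pd.Series   # group -> letter string
    mse: float
    df_error: int


def _duncan_letters(means: np.ndarray, nonsig: np.ndarray) -> list[str]:
    """Compact letter display for means sorted descending.

    ``nonsig[i, j]`` says the range from mean i to mean j (i <= j) is not
    significant.  Maximal non-significant contiguous runs each get one
    letter; every mean collects the letters of the runs covering it.
    """
    k = len(means)
    runs = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if not runs or runs[-1][1] < j or runs[-1][0] > i:
            runs.append((i, j))
        i += 1
    # drop runs fully contained in another
    maximal = [
        (a, b)
        for a, b in runs
        if not any((c <= a and b <= d) and (a, b) != (c, d) for c, d in runs)
    ]
    letters = [""] * k
    for letter_idx, (a, b) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_idx)
        for m in range(a, b + 1):
            letters[m] += ch
    return letters


def anova_duncan(groups: dict[str, np.ndarray], alpha: float = 0.05) -> DuncanResult:
    """One-way fixed-effects ANOVA and Duncan's multiple range test.

    ``groups`` maps subgroup name to its observations.  The range test
    uses studentized-range critical points at the protection level
    1 - (1 - alpha)^(r-1) for a range spanning r means, with the ANOVA MSE
    and its residual degrees of freedom; unequal group sizes use the
    harmonic-mean n.
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    data = [d[~np.isnan(d)] for d in data]
    if len(data) < 2:
        raise ValidationError("need at least 2 subgroups")
    if any(len(d) < 2 for d in data):
        raise ValidationError("every subgroup needs at least 2 observations")

    ns = np.array([len(d) for d in data])
    means = np.array([d.mean() for d in data])
    n_tot = int(ns.sum())
    grand = np.concatenate(data).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    df_b, df_e = len(data) - 1, n_tot - len(data)
    if ss_within == 0:
        raise ValidationError("zero within-group variance: F undefined")
    mse = ss_within / df_e
    f_stat = (ss_between / df_b) / mse
    p_value = float(stats.f.sf(f_stat, df_b, df_e))

    order = np.argsort(means)[::-1]
    sorted_means = means[order]
    n_h = len(ns) / np.sum(1.0 / ns)  # harmonic mean group size
    se = math.sqrt(mse / n_h)

    k = len(data)
    lsr = {r: stats.studentized_range.ppf(
        (1 - alpha) ** (r - 1), r, df_e) * se for r in range(2, k + 1)}

    # Duncan's protected sweep: largest ranges first, a non-significant
    # range shields all its sub-ranges
    nonsig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:
                continue
            if sorted_means[i] - sorted_means[j] <= lsr[span]:
                for a in range(i, j + 1):
                    for b in range(a, j + 1):
                        nonsig[a, b] = True
    letters = _duncan_letters(sorted_means, nonsig)

    idx = [names[i] for i in order]
    return DuncanResult(
        f_stat=float(f_stat),
        p_value=p_value,
        alpha=alpha,
        means=pd.Series(sorted_means, index=idx, name="mean"),
        letters=pd.Series(letters, index=idx, name="letters"),
        mse=float(mse),
        df_error=df_e,
    )


def anova_duncan_table(
    table: pd.DataFrame, subgroup: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Run anova_duncan per trait column; listwise deletion within a trait.

    Returns one row per trait: F, p and per-subgroup ``mean (letter)``.
    """
    rows = []
    for col in table.columns:
        vals = table[col]
        grp = {
            g: vals[subgroup == g].dropna().to_numpy()
            for g in subgroup.unique()
        }
        res = anova_duncan(grp, alpha)
        row = {"trait": col, "F": res.f_stat, "p": res.p_value}
        for g in res.means.index:
            row[f"mean_{g}"] = res.means[g]
            row[f"letters_{g}"] = res.letters[g]
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")


def plot_correlation_heatmap(rho: pd.DataFrame, path) -> None:
    """Plain correlation heatmap written to ``path`` (matplotlib Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 8))
    im = ax.imshow(rho.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho.columns)))
    ax.set_xticklabels(rho.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rho.index)))
    ax.set_yticklabels(rho.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
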