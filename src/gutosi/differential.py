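"""Two-group differential-feature detection.

Taxa go through a LEfSe-style procedure: a Kruskal-Wallis screen (exact
by enumeration at small sample sizes) followed by a bootstrapped linear
discriminant analysis (LDA) effect size on the per-million scale, with
significance declared at P < 0.05 AND LDA score > 2.  Metabolites and
pathway/KO abundances use the Wilcoxon rank-sum test at P < 0.05 with a
HOS/LOS fold change.  Benjamini-Hochberg-adjusted columns are always
emitted for transparency but the flags follow the raw-p conventions
above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from . import exact

logger = logging.getLogger(__name__)

LDA_SCORE_CUTOFF = 2.0
ALPHA = 0.05

#: per-group cap for the exact Wilcoxon path; above it, the normal
#: approximation with tie/continuity correction is used
WILCOXON_EXACT_MAX = 25


@dataclass
class LefseResult:
    table: pd.DataFrame  # feature rows: statistic, pvalue, lda_score, significant, ...
    group_order: tuple[str, str]
    seed: int


def _group_arrays(table: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    groups = groups.reindex(table.index)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    return {g: table.loc[groups == g] for g in pd.unique(groups)}


def kruskal_wallis_screen(table: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis H with tie correction.

    Exact enumeration p-values whenever the number of multiset rank
    assignments is tractable (covers the study's 9 + 9 design); the
    chi-square approximation otherwise.  Constant features get p = 1 and
    a ``constant`` flag.
    """
    parts = _group_arrays(table, groups)
    if len(parts) < 2:
        raise ValueError("need at least two groups")
    sizes = tuple(len(v) for v in parts.values())
    if min(sizes) < 2:
        raise ValueError("every group needs at least 2 samples")
    use_exact = exact.n_multiset_assignments(sizes) <= exact.KW_EXACT_LIMIT
    rows = []
    for feat in table.columns:
        vals = [v[feat].to_numpy(dtype=float) for v in parts.values()]
        pooled = np.concatenate(vals)
        if np.ptp(pooled) == 0:
            rows.append({"feature": feat, "statistic": 0.0, "pvalue": 1.0,
                         "constant": True, "method": "constant"})
            continue
        if use_exact:
            h, p = exact.kruskal_exact(vals)
            method = "exact"
        else:
            h, p = stats.kruskal(*vals)
            method = "chi2"
        rows.append({"feature": feat, "statistic": float(h), "pvalue": float(p),
                     "constant": False, "method": method})
    out = pd.DataFrame(rows).set_index("feature")
    out["pvalue_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def _to_per_million(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("sample with non-positive total; cannot rescale")
    return table.div(totals, axis=0) * 1e6


def lda_effect_size(
    table: pd.DataFrame,
    groups: pd.Series,
    n_boot: int = 30,
    subsample: float = 2 / 3,
    seed: int = 0,
) -> pd.Series:
    """Bootstrapped LDA effect size per feature, on the log10 scale.

    Rows are rescaled to per-million of each sample's total (the
    conventional LEfSe scale, on which the score-2 threshold operates).
    For each of ``n_boot`` bootstraps a stratified subsample (fraction
    ``subsample`` of each class, without replacement) is drawn and a
    shrinkage-regularized two-class LDA is fitted.  The per-feature
    effect is 0.5 * (|w_f * d| + |delta_f|), where w_f is the feature's
    discriminant coefficient, d the projected class-mean difference and
    delta_f the raw class-mean difference; the score is
    log10(1 + mean bootstrap effect).  Deterministic given ``seed``.
    """
    parts = _group_arrays(table, groups)
    if len(parts) != 2:
        raise ValueError("LDA effect size is defined for exactly two groups")
    scaled = _to_per_million(table)
    names = sorted(parts)
    a_idx = scaled.index[groups.reindex(scaled.index) == names[0]]
    b_idx = scaled.index[groups.reindex(scaled.index) == names[1]]
    na, nb = len(a_idx), len(b_idx)
    ka = max(2, int(np.ceil(subsample * na)))
    kb = max(2, int(np.ceil(subsample * nb)))
    rng = np.random.default_rng(seed)
    F = scaled.shape[1]
    effects = np.zeros(F)
    X_all = scaled.to_numpy(dtype=float)
    pos_a = {s: i for i, s in enumerate(scaled.index)}
    ia = np.array([pos_a[s] for s in a_idx])
    ib = np.array([pos_a[s] for s in b_idx])
    for _ in range(n_boot):
        for _attempt in range(10):
            sa = rng.choice(ia, size=ka, replace=False)
            sb = rng.choice(ib, size=kb, replace=False)
            if len(sa) and len(sb):
                break
        else:  # pragma: no cover - stratified draw cannot empty a class
            raise RuntimeError("a class vanished from the subsample repeatedly")
        Xa, Xb = X_all[sa], X_all[sb]
        X = np.vstack([Xa, Xb])
        ylab = np.array([0] * len(sa) + [1] * len(sb))
        keep = X.var(axis=0) > 0
        w = np.zeros(F)
        if keep.any():
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(X[:, keep], ylab)
            w[keep] = clf.coef_[0]
        mu_diff = Xb.mean(axis=0) - Xa.mean(axis=0)
        d = float(w @ mu_diff)
        effects += 0.5 * (np.abs(w * d) + np.abs(mu_diff))
    effects /= n_boot
    score = np.log10(1.0 + effects)
    return pd.Series(score, index=scaled.columns, name="lda_score")


def lefse(
    table: pd.DataFrame,
    groups: pd.Series,
    n_boot: int = 30,
    subsample: float = 2 / 3,
    seed: int = 0,
    alpha: float = ALPHA,
    lda_cutoff: float = LDA_SCORE_CUTOFF,
) -> LefseResult:
    """Full LEfSe-style differential-taxon analysis.

    Kruskal-Wallis screen + LDA effect size; a taxon is significant iff
    p < alpha AND LDA score > lda_cutoff.
    """
    screen = kruskal_wallis_screen(table, groups)
    scores = lda_effect_size(table, groups, n_boot=n_boot, subsample=subsample, seed=seed)
    parts = _group_arrays(table, groups)
    names = sorted(parts)
    means = pd.DataFrame({f"mean_{g}": parts[g].mean(axis=0) for g in names})
    higher = means.idxmax(axis=1).str.replace("mean_", "", regex=False)
    out = screen.join(scores).join(means)
    out["higher_in"] = higher
    out["significant"] = (out["pvalue"] < alpha) & (out["lda_score"] > lda_cutoff)
    return LefseResult(table=out, group_order=tuple(names), seed=seed)


def wilcoxon_fold_change(
    table: pd.DataFrame,
    groups: pd.Series,
    numerator: str = "HOS",
    denominator: str = "LOS",
    alpha: float = ALPHA,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum test with a HOS/LOS fold change.

    Exact p-values for group sizes <= 25 without ties; the normal
    approximation with tie and continuity corrections above.  With
    ``log_scale=True`` the table holds log intensities and the fold
    change is exp(mean difference) — the geometric-mean ratio on the
    original scale (the rank-based p-value is unaffected by the log).
    On raw tables a non-positive group mean switches the fold change to
    a pseudo-count scale (half the smallest positive value in the
    table), flagged in the ``pseudo_count`` column.
    """
    parts = _group_arrays(table, groups)
    if set(parts) != {numerator, denominator}:
        raise ValueError(
            f"expected groups {{{numerator!r}, {denominator!r}}}, got {sorted(parts)}"
        )
    num, den = parts[numerator], parts[denominator]
    if len(num) < 2 or len(den) < 2:
        raise ValueError("every group needs at least 2 samples")
    positive = table.to_numpy(dtype=float)
    positive = positive[positive > 0]
    pseudo = float(positive.min()) / 2.0 if positive.size else 0.5
    rows = []
    for feat in table.columns:
        x = num[feat].to_numpy(dtype=float)
        y = den[feat].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            stat, p = float(len(x) * len(y)) / 2.0, 1.0
        else:
            has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            small = max(len(x), len(y)) <= WILCOXON_EXACT_MAX
            method = "exact" if (small and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        mx, my = float(x.mean()), float(y.mean())
        used_pseudo = False
        if log_scale:
            fc = float(np.exp(mx - my))
        elif mx > 0 and my > 0:
            fc = mx / my
        else:
            # shift both means onto a positive pseudo-count scale
            used_pseudo = True
            shift = pseudo - min(mx, my, 0.0)
            fc = (mx + shift) / (my + shift)
        rows.append({
            "feature": feat,
            f"mean_{numerator}": mx,
            f"mean_{denominator}": my,
            "fold_change": fc,
            "log2_fc": float(np.log2(fc)),
            "statistic": stat,
            "pvalue": p,
            "pseudo_count": used_pseudo,
            "higher_in": numerator if mx >= my else denominator,
        })
    out = pd.DataFrame(rows).set_index("feature")
    out["pvalue_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["pvalue"] < alpha
    return out
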