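"""Oxidative stress index, extreme-group selection, and group statistics.

The oxidative stress index (OSI) is the ratio of plasma total oxidative
status (TOS, reported in uM) to total antioxidant capacity (T-AOC,
reported in mM) after harmonizing both to a common concentration scale.
High- and low-OSI groups (HOS / LOS) of size k are the OSI extremes,
adjusted so that matching covariates (milk yield, parity, body condition
score) do not differ significantly between the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy import stats

#: multiplicative factors to a common scale (uM)
_UNIT_TO_UM = {"uM": 1.0, "μM": 1.0, "mM": 1000.0, "M": 1e6, "nM": 1e-3}

LOS, HOS = "LOS", "HOS"

#: significance bands used throughout: P <= 0.05 significant,
#: 0.05 < P <= 0.10 a "trend"
SIGNIFICANT_P = 0.05
TREND_P = 0.10


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    test_name: str
    group_summaries: pd.DataFrame  # columns: mean, sem, n
    pairwise: pd.DataFrame | None = None  # post-hoc t tests for >2 groups

    @property
    def significant(self) -> bool:
        return self.pvalue <= SIGNIFICANT_P

    @property
    def trend(self) -> bool:
        return SIGNIFICANT_P < self.pvalue <= TREND_P


@dataclass
class GroupAssignment:
    labels: pd.Series  # per-sample: LOS / HOS / unassigned
    k: int
    matching_report: pd.DataFrame  # per covariate: group means + p
    swaps: int = 0

    @property
    def los(self) -> list:
        return self.labels.index[self.labels == LOS].tolist()

    @property
    def hos(self) -> list:
        return self.labels.index[self.labels == HOS].tolist()


def compute_osi(tos, taoc, tos_unit: str = "uM", taoc_unit: str = "mM"):
    """OSI = TOS / T-AOC after converting both to a common scale.

    Accepts scalars or arrays.  T-AOC must be strictly positive — a zero
    or negative antioxidant capacity is an invalid assay value, not a
    computable ratio.
    """
    for unit in (tos_unit, taoc_unit):
        if unit not in _UNIT_TO_UM:
            raise ValueError(f"unknown concentration unit {unit!r}; "
                             f"known: {sorted(_UNIT_TO_UM)}")
    tos_um = np.asarray(tos, dtype=float) * _UNIT_TO_UM[tos_unit]
    taoc_um = np.asarray(taoc, dtype=float) * _UNIT_TO_UM[taoc_unit]
    if np.any(taoc_um <= 0):
        raise ValueError("T-AOC must be > 0 to form the OSI ratio")
    if np.any(tos_um < 0):
        raise ValueError("TOS must be non-negative")
    out = tos_um / taoc_um
    return float(out) if out.ndim == 0 else out


def compare_groups(values, groups) -> TestResult:
    """Two groups: pooled-variance Student's t test.  More: one-way ANOVA
    with unadjusted pairwise t tests as the post-hoc report.

    Identical degenerate groups (zero pooled variance, equal means) are
    reported as statistic 0, p = 1.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups), index=values.index)
    by = values.groupby(groups)
    sizes = by.size()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    summaries = pd.DataFrame({
        "mean": by.mean(),
        "sem": by.sem(ddof=1),
        "n": sizes,
    })
    arrays = [g.to_numpy() for _, g in by]
    if len(arrays) == 2:
        stat, p = _pooled_t(arrays[0], arrays[1])
        return TestResult(stat, p, "student_t", summaries)
    stat, p = stats.f_oneway(*arrays)
    if np.isnan(stat):  # all groups identical
        stat, p = 0.0, 1.0
    names = list(by.groups)
    rows = []
    for a, b in _combinations(range(len(arrays)), 2):
        t, pt = _pooled_t(arrays[a], arrays[b])
        rows.append({"group_a": names[a], "group_b": names[b],
                     "statistic": t, "pvalue": pt})
    pairwise = pd.DataFrame(rows)
    return TestResult(float(stat), float(p), "anova", summaries, pairwise)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=True)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate t test with unequal means and zero variance")
    return stat, p


def select_extreme_groups(
    phenotypes: pd.DataFrame,
    k: int,
    matching: list[str] | None = None,
    match_alpha: float = 0.10,
    osi_col: str = "OSI",
    max_swaps: int = 200,
) -> GroupAssignment:
    """Select the k lowest- and k highest-OSI samples with matched covariates.

    Deterministic greedy procedure: start from the strict OSI extremes,
    then, while any matching covariate differs between the groups at
    ``match_alpha``, try replacing one selected sample with the
    next-ranked unused candidate on the same tail and keep the swap that
    most improves the worst covariate p-value.  Raises (carrying the best
    attempt) if no matched assignment is found within ``max_swaps``.
    """
    matching = list(matching or [])
    if osi_col not in phenotypes.columns:
        raise ValueError(f"phenotype table has no {osi_col!r} column")
    osi = phenotypes[osi_col]
    if osi.isna().any():
        raise ValueError("OSI missing for some samples")
    n = len(phenotypes)
    if 2 * k > n:
        raise ValueError(f"cannot select 2x{k} groups from {n} samples")
    if np.ptp(osi.to_numpy()) == 0:
        raise ValueError("all OSI values equal; no extremes to select")
    for cov in matching:
        if cov not in phenotypes.columns:
            raise ValueError(f"matching covariate {cov!r} not in table")

    # stable order: OSI then sample id, so ties break deterministically
    order = phenotypes.assign(_osi=osi).sort_values(
        ["_osi"], kind="mergesort"
    ).index.tolist()
    low_pool = order  # ascending OSI
    high_pool = order[::-1]  # descending

    low_sel = list(low_pool[:k])
    high_sel = list(high_pool[:k])

    def report(los: list, hos: list) -> pd.DataFrame:
        rows = []
        for cov in matching:
            a = phenotypes.loc[los, cov].to_numpy(dtype=float)
            b = phenotypes.loc[hos, cov].to_numpy(dtype=float)
            _, p = _pooled_t(a, b)
            rows.append({"covariate": cov, "mean_LOS": a.mean(),
                         "mean_HOS": b.mean(), "pvalue": p})
        return pd.DataFrame(rows)

    def worst_p(rep: pd.DataFrame) -> float:
        return float(rep["pvalue"].min()) if len(rep) else 1.0

    rep = report(low_sel, high_sel)
    swaps = 0
    window = 10  # how many next-ranked unused candidates to consider per tail
    while worst_p(rep) <= match_alpha and swaps < max_swaps:
        best = None  # (worst_p, side, trial, report)
        used = set(low_sel) | set(high_sel)
        for side, sel, pool in (("low", low_sel, low_pool),
                                ("high", high_sel, high_pool)):
            candidates = [s for s in pool if s not in used][:window]
            for nxt in candidates:
                for i in range(k):
                    trial = sel.copy()
                    trial[i] = nxt
                    los = trial if side == "low" else low_sel
                    hos = trial if side == "high" else high_sel
                    r = report(los, hos)
                    score = worst_p(r)
                    if best is None or score > best[0]:
                        best = (score, side, trial, r)
        if best is None or best[0] <= worst_p(rep):
            raise ValueError(
                "no covariate-matched extreme groups found; best attempt: "
                f"min p = {worst_p(rep):.4f}\n{rep}"
            )
        _, side, trial, rep = best
        if side == "low":
            low_sel = trial
        else:
            high_sel = trial
        swaps += 1
    if worst_p(rep) <= match_alpha:
        raise ValueError(
            f"matching failed after {swaps} swaps; best attempt min p = "
            f"{worst_p(rep):.4f}\n{rep}"
        )

    labels = pd.Series("unassigned", index=phenotypes.index, name="group")
    labels.loc[low_sel] = LOS
    labels.loc[high_sel] = HOS
    return GroupAssignment(labels=labels, k=k, matching_report=rep, swaps=swaps)
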