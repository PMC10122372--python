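"""Metabolomics table processing: QC filtering, probabilistic quotient
normalization (PQN), metabolite origin partitioning, and hypergeometric
pathway enrichment.

The QC filter keeps features detected (non-missing and > 0) in at least
half of the QC injections and with a QC relative standard deviation
(population SD / mean) of at most 30%.  PQN divides each biological
sample by the median, over features, of its intensity ratio to a
reference profile (the feature-wise median of the QC samples), which
removes per-sample dilution; intensities are then natural-log
transformed with a small additive offset.

Origins follow the four-way reporting convention of metabolite-origin
databases: host, microbiota, cometabolism, and "others" (drug + food +
environment + unknown).  Enrichment is the one-sided hypergeometric tail
per pathway, run within each origin category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

QC_FLAG = "is_qc"
ORIGIN_CATEGORIES = ("host", "microbiota", "cometabolism", "drug", "food",
                     "environment", "unknown")
OTHERS = ("drug", "food", "environment", "unknown")


@dataclass
class MetaboliteTable:
    """Sample x feature intensity table with QC flags and a processing state."""

    intensities: pd.DataFrame
    qc_samples: list[str]
    state: str = "raw"  # raw -> pqn -> pqn+log

    def __post_init__(self):
        missing = [s for s in self.qc_samples if s not in self.intensities.index]
        if missing:
            raise ValueError(f"QC samples absent from table: {missing}")
        vals = self.intensities.to_numpy(dtype=float)
        if vals.size and self.state == "raw" and np.nanmin(vals) < 0:
            raise ValueError("raw intensities must be non-negative or missing")

    @property
    def biological(self) -> pd.DataFrame:
        return self.intensities.drop(index=self.qc_samples)

    @property
    def qc(self) -> pd.DataFrame:
        return self.intensities.loc[self.qc_samples]


@dataclass
class QCFilterResult:
    table: MetaboliteTable
    removed_presence: list[str] = field(default_factory=list)
    removed_rsd: list[str] = field(default_factory=list)


@dataclass
class PQNResult:
    table: MetaboliteTable
    quotients: pd.Series  # per biological sample dilution quotient
    reference: pd.Series
    log_offset: float | None
    excluded_features: list[str] = field(default_factory=list)


def _detected(values: pd.DataFrame) -> pd.DataFrame:
    return values.notna() & (values > 0)


def qc_filter(
    table: MetaboliteTable,
    qc_presence_min: float = 0.5,
    rsd_max: float = 0.30,
) -> QCFilterResult:
    """Remove features undetected in < ``qc_presence_min`` of QC samples or
    with QC RSD strictly above ``rsd_max``.

    RSD = population SD / mean over the detected QC intensities.
    """
    if len(table.qc_samples) < 3:
        raise ValueError("need at least 3 QC samples for the QC filter")
    qc = table.qc
    det = _detected(qc)
    presence = det.mean(axis=0)
    keep_presence = presence >= qc_presence_min
    removed_presence = table.intensities.columns[~keep_presence].tolist()

    removed_rsd = []
    keep = keep_presence.copy()
    for feat in table.intensities.columns[keep_presence]:
        vals = qc[feat][det[feat]].to_numpy(dtype=float)
        mean = vals.mean()
        rsd = vals.std(ddof=0) / mean if mean > 0 else np.inf
        # strictly above the bound, with a round-off guard so a feature
        # sitting exactly at rsd_max is retained
        if rsd > rsd_max + 1e-12:
            keep[feat] = False
            removed_rsd.append(feat)
    filtered = MetaboliteTable(
        intensities=table.intensities.loc[:, keep],
        qc_samples=list(table.qc_samples),
        state=table.state,
    )
    return QCFilterResult(filtered, removed_presence, removed_rsd)


def pqn_normalize(
    table: MetaboliteTable,
    reference: pd.Series | None = None,
    log_transform: bool = True,
) -> PQNResult:
    """Probabilistic quotient normalization, then (optionally) natural log.

    Each sample's quotient is the median over features of
    intensity / reference; dividing by it removes per-sample dilution.
    The reference defaults to the feature-wise median of the QC samples
    (median of all samples if there are none).  Features with a
    non-positive reference are excluded from quotient computation and
    logged.  The log transform is ln(value + offset) with offset = half
    the minimum positive intensity, recorded in the result.
    """
    if table.state != "raw":
        raise ValueError(f"PQN expects a raw table, got state {table.state!r}")
    X = table.intensities
    if reference is None:
        source = table.qc if table.qc_samples else X
        reference = source.median(axis=0)
    reference = reference.reindex(X.columns)
    usable = reference.notna() & (reference > 0)
    excluded = X.columns[~usable].tolist()
    if excluded:
        logger.info("PQN: %d features excluded from quotients (non-positive "
                    "reference)", len(excluded))
    if not usable.any():
        raise ValueError("reference has no positive features; PQN undefined")

    quotients = {}
    normalized = X.copy().astype(float)
    for s in X.index:
        if s in table.qc_samples:
            continue
        ratios = (X.loc[s, usable] / reference[usable]).to_numpy(dtype=float)
        ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
        if ratios.size == 0:
            raise ValueError(f"sample {s!r} shares no positive features with "
                             "the reference")
        q = float(np.median(ratios))
        quotients[s] = q
        normalized.loc[s] = X.loc[s] / q
    state = "pqn"
    offset = None
    if log_transform:
        pos = normalized.to_numpy(dtype=float)
        pos = pos[np.isfinite(pos) & (pos > 0)]
        offset = float(pos.min()) / 2.0
        normalized = np.log(normalized + offset)
        state = "pqn+log"
    out = MetaboliteTable(
        intensities=normalized, qc_samples=list(table.qc_samples), state=state
    )
    return PQNResult(out, pd.Series(quotients, name="quotient"),
                     reference, offset, excluded)


@dataclass
class OriginAnnotation:
    """feature id -> origin category and pathway memberships."""

    origins: pd.Series  # values in ORIGIN_CATEGORIES
    pathways: dict[str, set[str]]  # feature -> pathway ids

    def __post_init__(self):
        if self.origins.index.duplicated().any():
            dupes = self.origins.index[self.origins.index.duplicated()].tolist()
            raise ValueError(f"duplicate origin annotations: {dupes}")
        bad = set(self.origins.unique()) - set(ORIGIN_CATEGORIES)
        if bad:
            raise ValueError(f"unknown origin categories: {sorted(bad)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OriginAnnotation":
        """Build from a table with columns ``origin`` and ``pathways``
        (semicolon-separated pathway ids), indexed by feature id."""
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate origin annotations: {dupes}")
        paths = {}
        for feat, cell in df.get("pathways", pd.Series(dtype=object)).items():
            if isinstance(cell, str) and cell:
                paths[feat] = set(cell.split(";"))
            else:
                paths[feat] = set()
        return cls(origins=df["origin"], pathways=paths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "origin": self.origins,
            "pathways": pd.Series({f: ";".join(sorted(p))
                                   for f, p in self.pathways.items()}),
        })


def classify_origins(features, annotation: OriginAnnotation) -> tuple[pd.Series, dict[str, list[str]]]:
    """Partition features into host / microbiota / cometabolism / others.

    Unannotated features count as unknown (hence others).  Returns the
    four-way counts (which always sum to the number of input features)
    and the per-category feature lists.
    """
    features = list(features)
    lists: dict[str, list[str]] = {"host": [], "microbiota": [],
                                   "cometabolism": [], "others": []}
    for feat in features:
        origin = annotation.origins.get(feat, "unknown")
        key = origin if origin in ("host", "microbiota", "cometabolism") else "others"
        lists[key].append(feat)
    counts = pd.Series({k: len(v) for k, v in lists.items()}, name="count")
    return counts, lists


def pathway_enrichment(
    differential,
    universe,
    annotation: OriginAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric pathway enrichment, per origin category.

    Within each category the universe is the annotated features of that
    category; with N such features, K in the pathway, and n differential,
    the p-value is P(X >= k) for X ~ Hypergeom(N, K, n).  Pathways with
    no universe member are skipped (logged).
    """
    differential = set(differential)
    universe = set(universe)
    if not differential <= universe:
        raise ValueError("differential features must be a subset of the universe")
    counts, lists = classify_origins(universe, annotation)
    rows = []
    for category in ("host", "microbiota", "cometabolism", "others"):
        cat_universe = set(lists[category])
        cat_diff = differential & cat_universe
        pathways: set[str] = set()
        for feat in cat_universe:
            pathways |= annotation.pathways.get(feat, set())
        for pw in sorted(pathways):
            members = {f for f in cat_universe if pw in annotation.pathways.get(f, set())}
            if not members:
                logger.info("pathway %s absent from %s universe; skipped", pw, category)
                continue
            N, K, n = len(cat_universe), len(members), len(cat_diff)
            k = len(cat_diff & members)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append({"pathway": pw, "origin": category, "k": k, "K": K,
                         "n": n, "N": N, "pvalue": p, "significant": p < alpha})
    return pd.DataFrame(rows)
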