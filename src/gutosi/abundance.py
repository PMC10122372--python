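"""Relative-abundance normalization and the prevalence-abundance filter.

The filter retains taxa whose relative abundance exceeds ``min_abundance``
(default 0.01%) in strictly more than ``min_prevalence`` (default 50%) of
samples — the standard screen applied to 16S/metagenome genus tables before
relationship-matrix, differential and network analysis.  Filtered tables
are deliberately NOT re-closed: every downstream consumer standardizes
each taxon column independently, so re-closure would change results
without justification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FilterResult:
    table: pd.DataFrame
    removed: list[str] = field(default_factory=list)
    min_abundance: float = 1e-4
    min_prevalence: float = 0.5


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a sample x taxon count table to relative abundances.

    Each row is divided by its total so rows sum to 1.  An all-zero
    sample is an error (it has no composition), reported by name.
    """
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    totals = vals.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        names = counts.index[zero].tolist()
        raise ValueError(f"sample(s) with zero total count: {names}")
    out = counts.astype(float).div(totals, axis=0)
    return out


def prevalence_filter(
    table: pd.DataFrame,
    min_abundance: float = 1e-4,
    min_prevalence: float = 0.5,
) -> FilterResult:
    """Keep taxa with abundance strictly > ``min_abundance`` in strictly
    more than ``min_prevalence`` of samples.

    Both boundaries are strict, reading "> 0.01% in more than 50% of the
    samples" literally.  Returns the filtered table (not re-closed) and
    the list of removed taxa.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must lie in [0, 1]")
    if min_abundance < 0:
        raise ValueError("min_abundance must be non-negative")
    frac_above = (table > min_abundance).mean(axis=0)
    keep = frac_above > min_prevalence
    removed = table.columns[~keep].tolist()
    if not keep.any():
        raise ValueError(
            "prevalence filter removed every taxon; review min_abundance/"
            "min_prevalence against the table's scale"
        )
    return FilterResult(
        table=table.loc[:, keep],
        removed=removed,
        min_abundance=min_abundance,
        min_prevalence=min_prevalence,
    )


def drop_zero_variance(table: pd.DataFrame) -> pd.DataFrame:
    """Drop taxa constant across samples (they carry no signal and break
    per-taxon standardization); logs what was removed."""
    variances = table.to_numpy(dtype=float).var(axis=0)
    keep = variances > 0
    dropped = table.columns[~keep].tolist()
    if dropped:
        logger.warning("dropping %d zero-variance taxa: %s", len(dropped), dropped[:10])
    return table.loc[:, keep]
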