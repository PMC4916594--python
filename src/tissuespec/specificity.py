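"""Tissue-specific transcript calling by fold change.

A transcript is specific to a tissue when its pseudocounted expression
there is at least ``fold_threshold`` times its maximum over every other
tissue (inclusive boundary: FC exactly equal to the threshold is a call).
On the log2 scale this is a difference of at least log2(fold_threshold).
Calls are labelled TSCT (tissue-specific coding transcript) or TSNT
(noncoding) via the merged biotype class. Fold change is computed on the
pseudocounted FPKM scale, so fold changes of weak expressors are
deliberately compressed toward 1 by the pseudocount.

Because the criterion compares a tissue against the max of all others, a
transcript can be specific to at most one tissue; a tie for the maximum
yields FC = 1 and hence no call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biotypes import PROTEIN_CODING

logger = logging.getLogger(__name__)

__all__ = [
    "SpecificityParams",
    "call_specific",
    "count_specific",
    "zscore_matrix",
]

TSCT = "TSCT"
TSNT = "TSNT"


@dataclass(frozen=True)
class SpecificityParams:
    """fold_threshold: minimum ratio of best tissue to runner-up (default 2,
    inclusive); pseudocount: added to FPKM before the ratio (default 0.1)."""

    fold_threshold: float = 2.0
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def call_specific(
    tissue_matrix: pd.DataFrame,
    params: SpecificityParams | None = None,
    annot: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call tissue-specific transcripts on a (filtered) tissue-level matrix.

    For each transcript, with v_t = FPKM_t + pseudocount, the fold change is
    v at the best tissue divided by the max v over the other tissues; the
    transcript is specific to the best tissue iff FC >= fold_threshold.
    Ties for the maximum are never specific (FC = 1 < threshold).

    Returns a DataFrame indexed by transcript_id with columns
    ``specific_tissue`` (tissue label or <NA>), ``fold_change`` and
    ``cls`` (TSCT/TSNT from ``annot.merged_class``, <NA> without one).
    """
    params = params or SpecificityParams()
    if tissue_matrix.shape[1] < 2:
        raise ValueError("specificity calling needs at least 2 tissues")
    v = tissue_matrix.to_numpy(dtype=float) + params.pseudocount
    order = np.argsort(v, axis=1)
    best = order[:, -1]
    rows = np.arange(v.shape[0])
    top = v[rows, best]
    second = v[rows, order[:, -2]]
    fc = top / second
    is_specific = fc >= params.fold_threshold

    tissues = tissue_matrix.columns.to_numpy()
    specific_tissue = pd.array(
        [tissues[b] if s else pd.NA for b, s in zip(best, is_specific)]
    )
    calls = pd.DataFrame(
        {"specific_tissue": specific_tissue, "fold_change": fc},
        index=tissue_matrix.index,
    )
    if annot is not None and "merged_class" in annot.columns:
        merged = annot["merged_class"].reindex(tissue_matrix.index)
        cls = np.where(merged == PROTEIN_CODING, TSCT, TSNT)
        calls["cls"] = pd.array([c if pd.notna(m) else pd.NA for c, m in zip(cls, merged)])
    else:
        calls["cls"] = pd.NA
    # at most one tissue per transcript by construction; assert the invariant
    assert calls.index.is_unique
    return calls


def count_specific(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue TSCT/TSNT counts, sorted by total descending.

    Transcripts with no call are excluded; transcripts lacking a class
    label are counted in an ``unclassified`` column.
    """
    called = calls[calls["specific_tissue"].notna()]
    if called.empty:
        return pd.DataFrame(columns=[TSCT, TSNT, "total"]).rename_axis("tissue")
    table = (
        called.assign(cls=called["cls"].fillna("unclassified"))
        .groupby(["specific_tissue", "cls"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    for col in (TSCT, TSNT):
        if col not in table.columns:
            table[col] = 0
    table["total"] = table.sum(axis=1)
    return table.sort_values("total", ascending=False).rename_axis("tissue")


def zscore_matrix(
    tissue_log: pd.DataFrame,
    calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize called transcripts' log2 profiles for heatmap display.

    Rows are restricted to called transcripts, z-scored per transcript
    (mean 0, sample s.d. 1 with ddof=1), grouped by specific tissue, with
    tissue blocks ordered by descending call count. Zero-variance rows are
    dropped with a warning. Returns the matrix and a transcript -> tissue
    block Series in row order.
    """
    called = calls[calls["specific_tissue"].notna()]
    if called.empty:
        raise ValueError("zscore_matrix: no specificity calls")
    ids = tissue_log.index.intersection(called.index)
    block = tissue_log.loc[ids]
    sd = block.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("zscore_matrix: dropping %d zero-variance rows", int(flat.sum()))
        block = block.loc[~flat]
        sd = sd.loc[~flat]
    z = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)

    tissue_of = called["specific_tissue"].loc[z.index]
    block_sizes = tissue_of.value_counts()
    tissue_order = {t: i for i, t in enumerate(block_sizes.index)}
    row_order = sorted(z.index, key=lambda t: (tissue_order[tissue_of[t]], str(t)))
    z = z.loc[row_order]
    return z, tissue_of.loc[row_order]
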