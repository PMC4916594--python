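"""Pseudocount/log transforms, replicate aggregation, low-expression
filtering, expressed-transcript detection and replicate concordance.

All downstream statistics operate on log2(FPKM + pseudocount) with a
pseudocount of 0.1. The relatively large pseudocount deliberately
compresses fold changes of weak expressors, acting as a soft threshold
that focuses analysis on clearly expressed transcripts.

Replicate aggregation uses the geometric mean of (FPKM + pseudocount)
across a tissue's technical-replicate libraries (minus the pseudocount,
floored at zero): this equals the arithmetic mean on the log2 scale the
analyses run on, so tissue-level log statistics are the replicate-average
log values. Arithmetic-mean aggregation on the FPKM scale is available as
an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biotypes import PROTEIN_CODING

__all__ = [
    "TransformParams",
    "aggregate_replicates",
    "filter_low_expression",
    "count_expressed",
    "log_transform",
    "replicate_concordance",
]


@dataclass(frozen=True)
class TransformParams:
    """Scalar knobs of the preprocessing stage.

    pseudocount
        Added to FPKM before log2 / geometric-mean / ratio computation
        (default 0.1). Must be > 0 for any log-scale operation.
    filter_threshold
        A transcript is retained iff the geometric mean over tissues of
        (FPKM + pseudocount) is >= this value (default 1.0; the boundary
        case of exactly 1 is retained).
    expressed_threshold
        A transcript counts as expressed in a library iff its raw FPKM is
        >= this value (default 1.0, inclusive; no pseudocount involved).
    """

    pseudocount: float = 0.1
    filter_threshold: float = 1.0
    expressed_threshold: float = 1.0

    log_base: int = 2  # fixed; field kept for provenance echo

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.log_base != 2:
            raise ValueError("log transform is fixed at base 2")


def _tissue_groups(samples: pd.DataFrame) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for row in samples.itertuples(index=False):
        groups.setdefault(row.tissue, []).append(row.sample_id)
    return groups


def aggregate_replicates(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    params: TransformParams | None = None,
    *,
    method: str = "geometric",
) -> pd.DataFrame:
    """Collapse technical-replicate libraries into one column per tissue.

    geometric (default): tissue value = geomean over the tissue's samples of
    (FPKM + pseudocount), minus the pseudocount, floored at 0. With a single
    replicate (or identical replicates) this is the identity.
    arithmetic: plain mean of FPKM.

    Tissue column order follows first appearance in the sample table.
    """
    params = params or TransformParams()
    groups = _tissue_groups(samples)
    if not groups:
        raise ValueError("sample table has no samples")
    missing = [s for ss in groups.values() for s in ss if s not in expr.columns]
    if missing:
        raise ValueError(f"samples absent from matrix: {missing[:5]}")
    cols = {}
    for tissue, sample_ids in groups.items():
        block = expr[sample_ids].to_numpy(dtype=float)
        if method == "geometric":
            if params.pseudocount <= 0:
                raise ValueError("geometric aggregation requires pseudocount > 0")
            log_mean = np.log2(block + params.pseudocount).mean(axis=1)
            cols[tissue] = np.maximum(np.exp2(log_mean) - params.pseudocount, 0.0)
        elif method == "arithmetic":
            cols[tissue] = block.mean(axis=1)
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
    return pd.DataFrame(cols, index=expr.index)


def filter_low_expression(
    tissue_matrix: pd.DataFrame,
    params: TransformParams | None = None,
) -> tuple[pd.DataFrame, pd.Index]:
    """Drop transcripts whose geometric mean of (FPKM + pseudocount) over
    tissues falls below ``filter_threshold``.

    The comparison is strict on the removal side: a transcript whose
    geometric mean is exactly the threshold is retained. Returns the
    retained matrix and the removed transcript ids (for audit).
    """
    params = params or TransformParams()
    if params.pseudocount <= 0:
        raise ValueError("low-expression filter requires pseudocount > 0")
    gm_log = np.log2(tissue_matrix.to_numpy(dtype=float) + params.pseudocount).mean(axis=1)
    retained = gm_log >= np.log2(params.filter_threshold)
    removed_ids = tissue_matrix.index[~retained]
    return tissue_matrix.loc[retained], removed_ids


def count_expressed(
    expr: pd.DataFrame,
    params: TransformParams | None = None,
    annot: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-library expressed-transcript counts on raw FPKM (no pseudocount).

    A transcript is expressed in a library iff FPKM >= expressed_threshold
    (inclusive). With an annotation carrying ``merged_class``, counts are
    split into coding/noncoding; otherwise a single ``all`` column.
    """
    params = params or TransformParams()
    detected = expr.to_numpy(dtype=float) >= params.expressed_threshold
    detected = pd.DataFrame(detected, index=expr.index, columns=expr.columns)
    if annot is None or "merged_class" not in getattr(annot, "columns", ()):
        return detected.sum(axis=0).to_frame("all").rename_axis("sample_id")
    merged = annot["merged_class"].reindex(expr.index)
    coding = merged == PROTEIN_CODING
    out = pd.DataFrame(
        {
            "coding": detected.loc[coding].sum(axis=0),
            "noncoding": detected.loc[~coding & merged.notna()].sum(axis=0),
        }
    )
    return out.rename_axis("sample_id")


def log_transform(matrix: pd.DataFrame, params: TransformParams | None = None) -> pd.DataFrame:
    """log2(value + pseudocount), elementwise."""
    params = params or TransformParams()
    if params.pseudocount <= 0:
        raise ValueError("log transform requires pseudocount > 0")
    return np.log2(matrix.astype(float) + params.pseudocount)


def replicate_concordance(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    annot: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman correlation between a tissue's technical replicates,
    split by coding/noncoding class when an annotation is bound.

    With exactly two replicates per tissue this is the replicate pair's
    coefficient; with more, all pairs are averaged. A single-replicate
    tissue yields NaN. Ties (common at FPKM 0) get average ranks.
    """
    groups = _tissue_groups(samples)
    if annot is not None and "merged_class" in annot.columns:
        merged = annot["merged_class"].reindex(expr.index)
        classes = {
            "coding": expr.index[(merged == PROTEIN_CODING).to_numpy()],
            "noncoding": expr.index[((merged != PROTEIN_CODING) & merged.notna()).to_numpy()],
        }
    else:
        classes = {"all": expr.index}

    rows = {}
    for tissue, sample_ids in groups.items():
        rows[tissue] = {}
        for cls, ids in classes.items():
            if len(sample_ids) < 2 or len(ids) < 2:
                rows[tissue][cls] = np.nan
                continue
            block = expr.loc[ids, sample_ids].to_numpy(dtype=float)
            coefs = []
            for i in range(len(sample_ids)):
                for j in range(i + 1, len(sample_ids)):
                    rho = stats.spearmanr(block[:, i], block[:, j]).statistic
                    coefs.append(rho)
            rows[tissue][cls] = float(np.mean(coefs))
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("tissue")
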