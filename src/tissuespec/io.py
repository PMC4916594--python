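"""Reading, writing and binding of expression matrices, sample metadata and
transcript annotations.

The canonical on-disk formats are tab-delimited UTF-8 text:

* expression matrix — header row, first column ``transcript_id``, one column
  per sample, FPKM values (non-negative reals);
* sample table — columns ``sample_id``, ``tissue``, ``site``;
* annotation — either a two-column TSV (``transcript_id``, ``biotype``) or a
  GTF whose transcript features carry ``transcript_id`` and a biotype
  attribute (``transcript_biotype`` by default; configurable because Ensembl
  GTF dialects differ across releases).

Row order is preserved on round trips.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_table",
    "write_sample_table",
    "read_annotation",
    "write_annotation_tsv",
    "validate_expression",
    "validate_sample_table",
    "BoundDataset",
    "bind",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def validate_expression(expr: pd.DataFrame, *, source: str = "expression matrix") -> pd.DataFrame:
    """Check an FPKM matrix (transcripts x samples): unique labels, numeric,
    finite, non-negative. Returns the matrix with a float dtype."""
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"{source}: duplicate transcript ids {dupes[:5]}")
    if expr.columns.has_duplicates:
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{source}: duplicate sample ids {dupes[:5]}")
    try:
        values = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{source}: non-numeric cell ({exc})") from exc
    if values.isna().any().any():
        row, col = next(zip(*np.nonzero(values.isna().to_numpy())))
        raise ValidationError(
            f"{source}: missing/non-numeric cell at transcript "
            f"{values.index[row]!r}, sample {values.columns[col]!r}"
        )
    if (values.to_numpy() < 0).any():
        row, col = next(zip(*np.nonzero((values < 0).to_numpy())))
        raise ValidationError(
            f"{source}: negative FPKM at transcript {values.index[row]!r}, "
            f"sample {values.columns[col]!r}"
        )
    return values


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read an FPKM matrix TSV (first column transcript_id, header row).

    Returns a validated transcripts x samples DataFrame of floats.
    Malformed numeric cells, missing cells, duplicate ids and negative
    values raise :class:`ValidationError` naming the offending cell.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    raw.index = raw.index.astype(str)
    # Parse column by column so we can name the offending cell.
    parsed = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            tid = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path.name}: malformed numeric cell at transcript {tid!r}, "
                f"sample {col!r}: {raw.loc[tid, col]!r}"
            )
        parsed[col] = numeric
    expr = pd.DataFrame(parsed, index=raw.index)
    return validate_expression(expr, source=path.name)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write an FPKM (or log-scale) matrix as TSV with a transcript_id column."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        expr.rename_axis("transcript_id").to_csv(fh, sep="\t")


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "tissue", "site"}
    missing = required - set(samples.columns)
    if missing:
        raise ValidationError(f"sample table missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValidationError("sample table: duplicate sample_id")
    if samples.duplicated(subset=["tissue", "site"]).any():
        raise ValidationError("sample table: duplicate (tissue, site) pair")
    return samples.reset_index(drop=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return validate_sample_table(samples)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# --- annotation ---------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr_field))


def read_annotation(
    path: str | Path,
    format: str = "tsv",
    *,
    biotype_key: str = "transcript_biotype",
) -> pd.DataFrame:
    """Read a transcript -> raw biotype annotation.

    Parameters
    ----------
    path:
        TSV with columns (transcript_id, biotype) or a GTF whose transcript
        features carry ``transcript_id`` and *biotype_key* attributes.
    format:
        ``"tsv"`` or ``"gtf"``.
    biotype_key:
        GTF attribute holding the biotype (default ``transcript_biotype``).

    Returns a DataFrame indexed by transcript_id with a ``raw_biotype``
    column. Unknown biotypes are preserved verbatim. A transcript listed
    twice with conflicting biotypes is an error.
    """
    path = Path(path)
    if format == "tsv":
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if table.shape[1] < 2:
            raise ValidationError(f"{path.name}: annotation TSV needs >= 2 columns")
        table = table.iloc[:, :2]
        table.columns = ["transcript_id", "raw_biotype"]
        records = list(table.itertuples(index=False, name=None))
    elif format == "gtf":
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValidationError(f"{path.name}:{lineno}: not a 9-column GTF line")
                if fields[2] != "transcript":
                    continue
                attrs = _parse_gtf_attributes(fields[8])
                if "transcript_id" not in attrs:
                    raise ValidationError(f"{path.name}:{lineno}: transcript feature lacks transcript_id")
                if biotype_key not in attrs:
                    raise ValidationError(
                        f"{path.name}:{lineno}: transcript feature lacks biotype "
                        f"attribute {biotype_key!r}"
                    )
                records.append((attrs["transcript_id"], attrs[biotype_key]))
    else:
        raise ValueError(f"unknown annotation format {format!r} (expected 'tsv' or 'gtf')")

    seen: dict[str, str] = {}
    order: list[str] = []
    for tid, biotype in records:
        if tid in seen:
            if seen[tid] != biotype:
                raise ValidationError(
                    f"{path.name}: transcript {tid!r} annotated with conflicting "
                    f"biotypes {seen[tid]!r} and {biotype!r}"
                )
            continue
        seen[tid] = biotype
        order.append(tid)
    annot = pd.DataFrame({"raw_biotype": [seen[t] for t in order]}, index=pd.Index(order, name="transcript_id"))
    return annot


def write_annotation_gtf(
    annot: pd.DataFrame,
    path: str | Path,
    *,
    biotype_key: str = "transcript_biotype",
) -> None:
    """Write the annotation as a minimal GTF of transcript features whose
    attributes carry transcript_id and the biotype (synthetic coordinates:
    one transcript per line on chromosome 1)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, (tid, row) in enumerate(annot.iterrows(), start=1):
            attrs = f'transcript_id "{tid}"; {biotype_key} "{row["raw_biotype"]}";'
            fh.write(f"1\ttissuespec\ttranscript\t{i * 1000}\t{i * 1000 + 500}\t.\t+\t.\t{attrs}\n")


def write_annotation_tsv(annot: pd.DataFrame, path: str | Path) -> None:
    out = annot.rename_axis("transcript_id").reset_index()
    cols = ["transcript_id", "raw_biotype"] + [c for c in out.columns if c not in ("transcript_id", "raw_biotype")]
    out[cols].to_csv(path, sep="\t", index=False)


# --- binding ------------------------------------------------------------


@dataclass
class BoundDataset:
    """A validated joint view of expression, sample metadata and annotation.

    ``expr`` is restricted to samples present in ``samples`` and (under the
    default drop policy) to annotated transcripts. ``n_unannotated`` counts
    transcripts dropped (or kept, under ``unannotated="keep"``) for lacking
    an annotation record.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame | None = None
    n_unannotated: int = 0
    unannotated_policy: str = "drop"
    log: list[str] = field(default_factory=list)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.columns


def bind(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    annot: pd.DataFrame | None = None,
    *,
    unannotated: str = "drop",
) -> BoundDataset:
    """Bind matrix, sample table and annotation into one validated dataset.

    Samples in the matrix must be a subset of the sample table (the table may
    list extra samples, which are dropped from the returned metadata).
    Transcripts without an annotation record are dropped (default) or kept
    flagged as ``unannotated``. Empty intersections are errors. bind is
    idempotent: binding a bound dataset's parts changes nothing.
    """
    if unannotated not in ("drop", "keep"):
        raise ValueError("unannotated policy must be 'drop' or 'keep'")
    expr = validate_expression(expr)
    samples = validate_sample_table(samples)

    known = set(samples["sample_id"])
    keep_samples = [s for s in expr.columns if s in known]
    if not keep_samples:
        raise ValidationError("bind: no overlap between matrix samples and sample table")
    expr = expr[keep_samples]
    samples = samples[samples["sample_id"].isin(keep_samples)].reset_index(drop=True)

    log = [f"bind: {len(keep_samples)} samples, {expr.shape[0]} transcripts"]
    n_unannotated = 0
    if annot is not None:
        annotated = expr.index.isin(annot.index)
        n_unannotated = int((~annotated).sum())
        if unannotated == "drop" and n_unannotated:
            expr = expr.loc[annotated]
            log.append(f"bind: dropped {n_unannotated} unannotated transcripts")
        elif n_unannotated:
            log.append(f"bind: kept {n_unannotated} unannotated transcripts")
        if expr.shape[0] == 0:
            raise ValidationError("bind: no transcripts remain after annotation intersection")
        annot = annot.loc[annot.index.intersection(expr.index)]
    for line in log:
        logger.info(line)
    return BoundDataset(
        expr=expr,
        samples=samples,
        annotation=annot,
        n_unannotated=n_unannotated,
        unannotated_policy=unannotated,
        log=log,
    )
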