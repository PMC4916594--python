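"""Biotype classification: protein-coding vs noncoding, and merging of raw
Ensembl biotypes into consolidated noncoding classes.

Everything that is not protein_coding counts as noncoding. Raw biotypes
are consolidated by an ordered rule list in which the first matching rule
wins: every pseudogene flavour (miRNA_pseudogene, snRNA_pseudogene,
IG_pseudogene, ...) merges into ``pseudogene``; the ``TR_*`` receptor-gene
biotypes merge into ``TR_gene``; the ``IG_*`` immunoglobulin biotypes merge
into ``IG_gene``. The pseudogene rule precedes the IG/TR prefix rules so
IG_pseudogene lands in pseudogene. Any biotype no rule matches maps to
itself, so the set of noncoding classes is emergent from the input
annotation rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "PROTEIN_CODING",
    "MergeRule",
    "default_rules",
    "merge_biotype",
    "classify",
    "tabulate_classes",
    "read_rules_tsv",
    "write_rules_tsv",
]

PROTEIN_CODING = "protein_coding"

#: accepted spelling variants for the immunoglobulin merged class
IG_GENE_ALIASES = ("IG_gene", "TG_gene")


@dataclass(frozen=True)
class MergeRule:
    """One pattern -> merged-class rule.

    match_mode is ``exact``, ``prefix`` or ``contains``; rules are applied
    in order and the first match wins.
    """

    pattern: str
    match_mode: str
    merged_class: str

    def matches(self, raw_biotype: str) -> bool:
        if self.match_mode == "exact":
            return raw_biotype == self.pattern
        if self.match_mode == "prefix":
            return raw_biotype.startswith(self.pattern)
        if self.match_mode == "contains":
            return self.pattern in raw_biotype
        raise ValueError(f"unknown match_mode {self.match_mode!r}")


def default_rules() -> list[MergeRule]:
    """The default consolidation rules (pseudogene before IG/TR prefixes)."""
    return [
        MergeRule("pseudogene", "contains", "pseudogene"),
        MergeRule("TR_", "prefix", "TR_gene"),
        MergeRule("IG_", "prefix", "IG_gene"),
        MergeRule(PROTEIN_CODING, "exact", PROTEIN_CODING),
    ]


def merge_biotype(raw_biotype: str, rules: list[MergeRule] | None = None) -> str:
    """Map one raw biotype to its merged class (identity if no rule matches)."""
    for rule in default_rules() if rules is None else rules:
        if rule.matches(raw_biotype):
            return rule.merged_class
    return raw_biotype


def classify(annot: pd.DataFrame, rules: list[MergeRule] | None = None) -> pd.DataFrame:
    """Populate ``merged_class`` from ``raw_biotype``.

    Total and deterministic: every transcript gets exactly one merged class;
    the protein-coding vs noncoding partition is derivable as
    ``merged_class == "protein_coding"``.
    """
    if "raw_biotype" not in annot.columns:
        raise ValueError("annotation lacks raw_biotype column")
    out = annot.copy()
    out["merged_class"] = [merge_biotype(b, rules) for b in annot["raw_biotype"]]
    return out


def tabulate_classes(
    annot: pd.DataFrame,
    restrict_to: pd.Index | set | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count and percentage tables for the coding/noncoding split and for
    the noncoding classes.

    Returns ``(split, noncoding)`` where *split* has rows protein_coding /
    noncoding with counts and percent of all (one decimal), and *noncoding*
    has one row per noncoding merged class with counts and percent of
    noncoding (nearest integer), sorted by count descending.
    """
    if "merged_class" not in annot.columns:
        raise ValueError("annotation lacks merged_class; run classify() first")
    sub = annot if restrict_to is None else annot.loc[annot.index.isin(set(restrict_to))]
    if sub.empty:
        raise ValueError("tabulate_classes: empty transcript set")
    merged = sub["merged_class"]
    n = len(merged)
    n_coding = int((merged == PROTEIN_CODING).sum())
    split = pd.DataFrame(
        {
            "count": [n_coding, n - n_coding],
            "percent": [round(100 * n_coding / n, 1), round(100 * (n - n_coding) / n, 1)],
        },
        index=pd.Index([PROTEIN_CODING, "noncoding"], name="class"),
    )
    nc = merged[merged != PROTEIN_CODING]
    counts = nc.value_counts()
    noncoding = pd.DataFrame(
        {
            "count": counts,
            "percent_of_noncoding": (100 * counts / len(nc)).round(0).astype(int) if len(nc) else counts,
        }
    ).rename_axis("class")
    return split, noncoding


def read_rules_tsv(path: str | Path) -> list[MergeRule]:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"pattern", "match_mode", "merged_class"}
    if not required.issubset(table.columns):
        raise ValueError(f"rules file needs columns {sorted(required)}")
    rules = [
        MergeRule(r.pattern, r.match_mode, r.merged_class)
        for r in table.itertuples(index=False)
    ]
    for rule in rules:
        if rule.match_mode not in ("exact", "prefix", "contains"):
            raise ValueError(f"unknown match_mode {rule.match_mode!r} in {path}")
    return rules


def write_rules_tsv(rules: list[MergeRule], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rules]).to_csv(path, sep="\t", index=False)
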