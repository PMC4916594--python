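"""Synthetic multi-tissue FPKM data with planted ground truth.

The generator emulates the statistical structure of a 14-tissue,
two-technical-replicate RNA-seq FPKM compendium:

* baseline expression is log2-normal on the FPKM scale (heavy-tailed, the
  standard working model for FPKM);
* each tissue is sequenced at ``n_sites`` sites; technical replicates are
  the tissue-level truth plus independent log2-scale Gaussian site noise,
  which reproduces high replicate concordance without modelling
  site-specific bias;
* a ``dropout_fraction`` of transcripts is forced to zero FPKM everywhere
  to exercise the low-expression filter;
* per tissue, ``n_specific_per_tissue`` transcripts are planted with an
  FPKM-scale fold elevation ``specific_fold`` in that tissue; their
  baseline is truncated below at FPKM 1 so the planted effect is
  identifiable after pseudocount attenuation and survives the
  low-expression filter (the pipeline's large pseudocount deliberately
  restricts specificity calling to clearly expressed transcripts);
* per tissue, ``module_size_per_tissue`` further transcripts form a
  co-expression block: each block shares a per-tissue latent factor
  (one N(0, module_factor_sd) draw per tissue, identical across that
  tissue's replicates) scaled by a per-transcript loading in [0.8, 1.0].
  Blocks are co-expressed but carry no mean shift, so block members are
  not tissue-specific;
* biotypes are protein_coding for ``n_coding`` transcripts and a
  multinomial draw over ``biotype_proportions`` for the ``n_noncoding``
  rest, shuffled over transcript ids so planted roles mix both classes.

The planted sets (specific, block, dropout) are disjoint. Identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSet, GeneSetCollection

__all__ = [
    "DEFAULT_BIOTYPE_PROPORTIONS",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_gene_sets",
    "write_simulation",
]

#: noncoding raw-biotype mix: mostly processed transcripts, lincRNAs and
#: pseudogene flavours, with a thin tail of small-RNA and IG/TR biotypes.
DEFAULT_BIOTYPE_PROPORTIONS: dict[str, float] = {
    "processed_transcript": 0.56,
    "lincRNA": 0.20,
    "processed_pseudogene": 0.10,
    "unprocessed_pseudogene": 0.05,
    "miRNA_pseudogene": 0.03,
    "antisense": 0.02,
    "snoRNA": 0.01,
    "snRNA": 0.01,
    "misc_RNA": 0.01,
    "IG_V_gene": 0.005,
    "TR_V_gene": 0.005,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study design (defaults are the reference
    configuration: 14 tissues x 2 sites, 5,000 transcripts, 40 planted
    specifics per tissue at fold 8, per-tissue blocks of 80, replicate
    noise 0.1 log2 units)."""

    n_tissues: int = 14
    n_sites: int = 2
    n_coding: int = 4500
    n_noncoding: int = 500
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS)
    )
    n_specific_per_tissue: int = 40
    specific_fold: float = 8.0
    module_size_per_tissue: int = 80
    module_factor_sd: float = 0.5
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    replicate_noise_sd: float = 0.1
    dropout_fraction: float = 0.16
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_tissues", "n_sites", "n_coding", "n_noncoding",
            "n_specific_per_tissue", "module_size_per_tissue",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_tissues < 1 or self.n_sites < 1:
            raise ValueError("need at least one tissue and one site")
        if self.n_coding + self.n_noncoding <= 0:
            raise ValueError("total transcript count must be positive")
        if self.specific_fold < 1:
            raise ValueError("specific_fold must be >= 1")
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError("dropout_fraction must be in [0, 1]")
        if self.replicate_noise_sd < 0 or self.module_factor_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        props = self.biotype_proportions
        if self.n_noncoding > 0:
            if not props:
                raise ValueError("biotype_proportions required when n_noncoding > 0")
            vals = np.fromiter(props.values(), dtype=float)
            if (vals < 0).any() or (vals > 1).any() or not np.isclose(vals.sum(), 1.0):
                raise ValueError("biotype_proportions must lie in [0,1] and sum to 1")
        n_planted = self.n_tissues * (self.n_specific_per_tissue + self.module_size_per_tissue)
        n_dropout = int(self.dropout_fraction * (self.n_coding + self.n_noncoding))
        if n_planted + n_dropout > self.n_coding + self.n_noncoding:
            raise ValueError(
                "planted specific/module/dropout transcripts exceed the total "
                f"transcript count ({n_planted} + {n_dropout} > {self.n_coding + self.n_noncoding})"
            )

    @property
    def n_transcripts(self) -> int:
        return self.n_coding + self.n_noncoding

    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    def site_names(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]


@dataclass
class SyntheticTruth:
    """Planted labels for recovery tests.

    specific_of / module_of / biotype_of map transcript ids to the planted
    tissue, co-expression block (named after its tissue) and raw biotype.
    ``tissue_level`` is the noise-free tissue-level FPKM profile (what
    replicate aggregation recovers at zero noise); ``dropout_ids`` the
    transcripts forced to zero.
    """

    specific_of: dict[str, str]
    module_of: dict[str, str]
    biotype_of: dict[str, str]
    tissue_level: pd.DataFrame
    dropout_ids: frozenset[str]
    config: SimulationConfig


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, sample table, annotation, truth).

    The matrix is transcripts x (n_tissues * n_sites) FPKM; sample ids are
    ``{tissue}_{site}``. Outputs are deterministic in the config (seed
    included).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    ids = np.array([f"T{i + 1:06d}" for i in range(n)])
    tissues = config.tissue_names()
    sites = config.site_names()
    sample_ids = [f"{t}_{s}" for t in tissues for s in sites]
    sample_tissue = np.array([t for t in tissues for _ in sites])

    # biotypes: coding block + multinomial noncoding draw, shuffled over ids
    biotypes = np.array(["protein_coding"] * config.n_coding, dtype=object)
    if config.n_noncoding:
        names = sorted(config.biotype_proportions)
        probs = np.array([config.biotype_proportions[k] for k in names])
        nc = rng.choice(names, size=config.n_noncoding, p=probs / probs.sum())
        biotypes = np.concatenate([biotypes, nc])
    rng.shuffle(biotypes)

    # role assignment over a random permutation: specifics, block members, dropouts
    perm = rng.permutation(n)
    cursor = 0
    specific_of: dict[str, str] = {}
    module_of: dict[str, str] = {}
    spec_idx: dict[str, np.ndarray] = {}
    mod_idx: dict[str, np.ndarray] = {}
    for t in tissues:
        take = perm[cursor:cursor + config.n_specific_per_tissue]
        cursor += config.n_specific_per_tissue
        spec_idx[t] = take
        specific_of.update({ids[i]: t for i in take})
    for t in tissues:
        take = perm[cursor:cursor + config.module_size_per_tissue]
        cursor += config.module_size_per_tissue
        mod_idx[t] = take
        module_of.update({ids[i]: t for i in take})
    n_dropout = int(config.dropout_fraction * n)
    dropout = perm[cursor:cursor + n_dropout]
    dropout_ids = frozenset(ids[dropout])

    # baseline log2 expression; planted specifics truncated at FPKM 1
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    all_spec = np.concatenate(list(spec_idx.values())) if specific_of else np.array([], dtype=int)
    mu[all_spec] = np.maximum(mu[all_spec], 0.0)

    # tissue-level log2 truth: baseline + specificity boost + latent factor
    log_tissue = np.tile(mu[:, None], (1, config.n_tissues))
    boost = np.log2(config.specific_fold)
    for ti, t in enumerate(tissues):
        log_tissue[spec_idx[t], ti] += boost
    loadings = np.zeros(n)
    # factor[m, t]: block m's latent value in tissue t (shared by its
    # replicates). Blocks are mutually orthogonal directions in tissue
    # space, scaled so entries have RMS module_factor_sd: each block is a
    # distinct tissue program, so planted membership is identifiable.
    factor = rng.normal(0.0, 1.0, size=(config.n_tissues, config.n_tissues))
    if config.n_tissues > 1:
        q, _ = np.linalg.qr(factor.T)
        factor = q.T[: config.n_tissues] * np.sqrt(config.n_tissues) * config.module_factor_sd
    else:
        factor = factor * config.module_factor_sd
    for mi, t in enumerate(tissues):
        members = mod_idx[t]
        loadings[members] = rng.uniform(0.8, 1.0, size=len(members))
        log_tissue[members, :] += loadings[members, None] * factor[mi, :][None, :]

    # library-level values: tissue truth + replicate noise, dropouts at 0
    tissue_col = {t: i for i, t in enumerate(tissues)}
    log_samples = log_tissue[:, [tissue_col[t] for t in sample_tissue]]
    if config.replicate_noise_sd > 0:
        log_samples = log_samples + rng.normal(
            0.0, config.replicate_noise_sd, size=log_samples.shape
        )
    fpkm = np.exp2(log_samples)
    fpkm[dropout, :] = 0.0
    tissue_level = np.exp2(log_tissue)
    tissue_level[dropout, :] = 0.0

    expr = pd.DataFrame(fpkm, index=pd.Index(ids, name="transcript_id"), columns=sample_ids)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": sample_tissue,
            "site": [s for _ in tissues for s in sites],
        }
    )
    annot = pd.DataFrame(
        {"raw_biotype": biotypes}, index=pd.Index(ids, name="transcript_id")
    )
    truth = SyntheticTruth(
        specific_of=specific_of,
        module_of=module_of,
        biotype_of=dict(zip(ids, biotypes)),
        tissue_level=pd.DataFrame(
            tissue_level, index=expr.index.copy(), columns=tissues
        ),
        dropout_ids=dropout_ids,
        config=config,
    )
    return expr, samples, annot, truth


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int,
    seed: int,
) -> GeneSetCollection:
    """Gene sets with one set per tissue built from that tissue's planted
    specific transcripts (plus random decoys), padded with random sets up
    to ``n_sets``.

    Requires n_sets >= number of tissues with planted specifics, so the
    per-tissue enriched set exists for every tissue. Deterministic in
    (truth, seed).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not truth.specific_of:
        raise ValueError("truth has no planted specific transcripts")
    rng = np.random.default_rng(seed)
    all_ids = sorted(truth.biotype_of)
    tissues = sorted(set(truth.specific_of.values()))
    if n_sets < len(tissues):
        raise ValueError(
            f"n_sets={n_sets} < {len(tissues)} tissues; need one set per tissue"
        )
    by_tissue: dict[str, list[str]] = {t: [] for t in tissues}
    for tid, t in sorted(truth.specific_of.items()):
        by_tissue[t].append(tid)

    sets = []
    for t in tissues:
        members = list(by_tissue[t])
        n_decoys = max(2 - len(members), int(round(0.3 * len(members))))
        decoys = rng.choice(all_ids, size=n_decoys, replace=False)
        sets.append(
            GeneSet(
                name=f"{t}_signature",
                description=f"planted specific transcripts of {t} plus decoys",
                members=frozenset(members) | frozenset(decoys),
            )
        )
    for i in range(n_sets - len(tissues)):
        size = int(rng.integers(5, 51))
        members = rng.choice(all_ids, size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"random_set_{i + 1:03d}",
                description="random background set",
                members=frozenset(members),
            )
        )
    return GeneSetCollection(sets)


def write_simulation(
    out_dir: str | Path,
    config: SimulationConfig,
    *,
    n_gene_sets: int | None = None,
) -> dict[str, Path]:
    """Run the generator and write matrix/metadata/annotation (and a GMT
    when ``n_gene_sets`` is given) under ``out_dir``. Returns the paths."""
    from . import io as tio
    from .enrich import write_gmt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr, samples, annot, truth = simulate_expression(config)
    paths = {
        "matrix": out_dir / "expression_fpkm.tsv",
        "samples": out_dir / "samples.tsv",
        "annotation": out_dir / "annotation.tsv",
    }
    tio.write_expression_tsv(expr, paths["matrix"])
    tio.write_sample_table(samples, paths["samples"])
    tio.write_annotation_tsv(annot, paths["annotation"])
    truth_table = pd.DataFrame(
        {
            "specific_of": pd.Series(truth.specific_of),
            "module_of": pd.Series(truth.module_of),
            "dropout": pd.Series({t: True for t in truth.dropout_ids}),
        }
    ).rename_axis("transcript_id")
    paths["truth"] = out_dir / "truth.tsv"
    truth_table.to_csv(paths["truth"], sep="\t")
    if n_gene_sets is not None:
        collection = simulate_gene_sets(truth, n_gene_sets, seed=config.seed)
        paths["gmt"] = out_dir / "gene_sets.gmt"
        write_gmt(collection, paths["gmt"])
    return paths
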