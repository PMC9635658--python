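"""Seeded synthetic fixtures emulating the real inputs of the pipeline.

Three generators cover everything the other modules consume:

* :func:`simulate_feature_table` — a gene x feature table with planted
  class signal (informative features location-shifted for positives),
  correlated feature blocks driven by shared latent factors, and optional
  missingness;
* :func:`simulate_genome` / :func:`simulate_prioritization_benchmark` — a
  toy multi-chromosome genome of non-overlapping gene spans arranged in
  well-separated windows, one planted causal gene per window whose feature
  row is drawn from the positive-class distribution;
* :func:`simulate_raw_inputs` — PPI / expression / annotation files in the
  exact external dialects the features module reads, with ground-truth
  feature values emitted alongside for oracle testing.

Default sizes mirror the shape of the real problem at a scale that keeps
test runs in minutes: 200 positives against a 5,000-gene negative pool,
20 features of which 3 are informative.  All generators are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import PPINetwork, _normalize_edge_frame
from .prioritize import GeneAnnotation, GeneLocus
from .table import FeatureTable, LabeledGeneSet

__all__ = [
    "SimConfig",
    "SimulatedTable",
    "SimulatedGenome",
    "PrioritizationBenchmark",
    "RawInputs",
    "simulate_feature_table",
    "simulate_genome",
    "simulate_prioritization_benchmark",
    "simulate_raw_inputs",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study conditions.

    ``effect_size`` is the location shift (in SD units of the standard
    normal noise) applied to informative features of positive genes.
    Correlated blocks are built from shared latent factors so that the
    expected within-block Pearson correlation equals ``block_corr``.
    """

    n_genes: int = 5200
    n_positives: int = 200
    n_features: int = 20
    n_informative: int = 3
    effect_size: float = 1.0
    n_correlated_blocks: int = 2
    block_size: int = 3
    block_corr: float = 0.8
    missing_rate: float = 0.0
    count_like: bool = False
    n_chromosomes: int = 5
    chromosome_length: int = 30_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.n_positives >= self.n_genes:
            raise ValueError("n_positives must be smaller than n_genes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.block_corr < 1.0:
            raise ValueError("block_corr must lie in [0, 1)")
        blocked = self.n_correlated_blocks * self.block_size
        if self.n_informative + blocked > self.n_features:
            raise ValueError(
                "informative features plus correlated blocks exceed n_features"
            )
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("invalid chromosome configuration")


@dataclass
class SimulatedTable:
    """Feature table with planted signal and its generating ground truth."""

    table: FeatureTable
    labels: LabeledGeneSet
    informative_features: list[str]
    correlated_blocks: list[list[str]]


def _feature_names(cfg: SimConfig) -> tuple[list[str], list[str], list[list[str]]]:
    names = [f"feat_{i:02d}" for i in range(cfg.n_features)]
    informative = names[: cfg.n_informative]
    blocks = []
    k = cfg.n_informative
    for _ in range(cfg.n_correlated_blocks):
        blocks.append(names[k : k + cfg.block_size])
        k += cfg.block_size
    return names, informative, blocks


def _gene_matrix(
    cfg: SimConfig, rng: np.random.Generator, n_genes: int, positive_mask: np.ndarray
) -> pd.DataFrame:
    """Draw the feature matrix: latent-factor blocks, shifted informatives."""
    names, informative, blocks = _feature_names(cfg)
    values = rng.standard_normal((n_genes, cfg.n_features))
    rho = cfg.block_corr
    for block in blocks:
        latent = rng.standard_normal(n_genes)
        for name in block:
            j = names.index(name)
            values[:, j] = math.sqrt(rho) * latent + math.sqrt(1 - rho) * values[:, j]
    if cfg.count_like:
        # skewed count-shaped columns for the plain noise features, mimicking
        # degree- and domain-count distributions
        plain = [n for n in names if n not in informative and all(n not in b for b in blocks)]
        for name in plain:
            j = names.index(name)
            values[:, j] = rng.negative_binomial(2, 0.3, size=n_genes).astype(float)
    for name in informative:
        j = names.index(name)
        values[positive_mask, j] += cfg.effect_size
    return pd.DataFrame(values, columns=names)


def simulate_feature_table(cfg: SimConfig) -> SimulatedTable:
    """Generate a labeled feature table under the configured conditions."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    pos_idx = rng.choice(cfg.n_genes, size=cfg.n_positives, replace=False)
    positive_mask = np.zeros(cfg.n_genes, dtype=bool)
    positive_mask[pos_idx] = True

    frame = _gene_matrix(cfg, rng, cfg.n_genes, positive_mask)
    frame.index = pd.Index(gene_ids)
    if cfg.missing_rate > 0:
        holes = rng.random(frame.shape) < cfg.missing_rate
        frame = frame.mask(holes)

    names, informative, blocks = _feature_names(cfg)
    positives = [gene_ids[i] for i in np.flatnonzero(positive_mask)]
    negatives = [gene_ids[i] for i in np.flatnonzero(~positive_mask)]
    return SimulatedTable(
        table=FeatureTable(frame),
        labels=LabeledGeneSet(positives, negatives),
        informative_features=informative,
        correlated_blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Toy genome with planted causal genes
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    """Gene loci arranged in separated windows, one planted causal gene each."""

    annotation: GeneAnnotation
    planted: list[str]
    window_members: dict[str, list[str]]


def simulate_genome(
    cfg: SimConfig,
    n_windows: int = 20,
    genes_per_window: int = 100,
    gene_length: int = 2_000,
    gene_spacing: int = 10_000,
    window_gap: int = 2_500_000,
) -> SimulatedGenome:
    """Place non-overlapping gene spans in well-separated windows.

    Each window is a contiguous run of ``genes_per_window`` genes spaced
    ``gene_spacing`` apart; windows on the same chromosome are separated by
    ``window_gap``, chosen larger than the 2 Mbp prioritization window so
    that a planted candidate's window contains exactly its own block.  The
    candidate is the window's middle gene.
    """
    if gene_length >= gene_spacing:
        raise ValueError("gene_length must be smaller than gene_spacing")
    rng = np.random.default_rng(cfg.seed + 1)
    span = genes_per_window * gene_spacing
    per_chrom = math.ceil(n_windows / cfg.n_chromosomes)
    if per_chrom * (span + window_gap) > cfg.chromosome_length:
        raise ValueError(
            "infeasible packing: chromosome_length too small for "
            f"{per_chrom} windows of span {span} plus gaps of {window_gap}"
        )
    loci: list[GeneLocus] = []
    planted: list[str] = []
    window_members: dict[str, list[str]] = {}
    for w in range(n_windows):
        chrom = f"chr{w % cfg.n_chromosomes + 1}"
        slot = w // cfg.n_chromosomes
        origin = 1 + slot * (span + window_gap)
        members = []
        for i in range(genes_per_window):
            gene_id = f"W{w:02d}G{i:03d}"
            start = origin + i * gene_spacing + int(rng.integers(0, gene_spacing - gene_length))
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(GeneLocus(gene_id, chrom, start, start + gene_length - 1, strand))
            members.append(gene_id)
        candidate = members[genes_per_window // 2]
        planted.append(candidate)
        window_members[candidate] = members
    return SimulatedGenome(
        annotation=GeneAnnotation(loci), planted=planted, window_members=window_members
    )


@dataclass
class PrioritizationBenchmark:
    """End-to-end fixture: genome, feature table, training labels, candidates.

    The table covers every genome gene plus a disjoint set of training
    positives; planted candidates and training positives share the
    positive-class feature distribution.  The negative pool is the genome
    minus the planted genes.
    """

    genome: SimulatedGenome
    table: FeatureTable
    labels: LabeledGeneSet
    candidates: list[str]


def simulate_prioritization_benchmark(
    cfg: SimConfig,
    n_windows: int = 20,
    genes_per_window: int = 100,
) -> PrioritizationBenchmark:
    """Build the planted-causal-gene benchmark for window prioritization."""
    genome = simulate_genome(cfg, n_windows=n_windows, genes_per_window=genes_per_window)
    genome_genes = genome.annotation.frame["gene_id"].tolist()
    train_pos = [f"P{i:04d}" for i in range(cfg.n_positives)]
    all_genes = genome_genes + train_pos
    positive_mask = np.array(
        [g in set(genome.planted) for g in genome_genes] + [True] * len(train_pos)
    )
    rng = np.random.default_rng(cfg.seed + 2)
    frame = _gene_matrix(cfg, rng, len(all_genes), positive_mask)
    frame.index = pd.Index(all_genes)
    table = FeatureTable(frame)
    pool = [g for g in genome_genes if g not in set(genome.planted)]
    labels = LabeledGeneSet(train_pos, pool)
    return PrioritizationBenchmark(
        genome=genome, table=table, labels=labels, candidates=list(genome.planted)
    )


# ---------------------------------------------------------------------------
# Raw-input files with ground truth
# ---------------------------------------------------------------------------

@dataclass
class RawInputs:
    """Paths of the generated raw files plus the ground-truth feature table."""

    paths: dict[str, Path]
    truth: pd.DataFrame
    network: PPINetwork


_TISSUES = ["flower", "root", "male organ", "seeds", "female organ",
            "stem", "leaf", "apical meristem", "root meristem"]
_ACCESSIONS = ["Zu-0", "Wu-0", "Ws-0", "Wil-2", "Tsu-0", "Sf-2", "Rsch-4",
               "Po-0", "Oy-0", "No-0", "Mt-0", "Ler-0", "Kn-0", "Hi-0",
               "Edi-0", "Ct-1", "Col-0", "Can-0", "Bur-0"]


def _write_expression(
    rng: np.random.Generator,
    genes: list[str],
    groups: list[str],
    reps: int,
    out_values: Path,
    out_meta: Path,
    classes: dict[str, str] | None = None,
    constant_gene: str | None = None,
) -> pd.DataFrame:
    """Write one expression matrix + metadata; return the value frame."""
    samples, meta_rows = [], []
    for g_i, group in enumerate(groups):
        for r in range(reps):
            sid = f"s{g_i:02d}_{r}"
            samples.append(sid)
            meta_rows.append((sid, group, classes[group] if classes else None))
    values = np.round(rng.lognormal(mean=2.0, sigma=1.0, size=(len(genes), len(samples))), 4)
    frame = pd.DataFrame(values, index=genes, columns=samples)
    if constant_gene is not None:
        frame.loc[constant_gene] = 7.0
    frame.index.name = "gene_id"
    frame.to_csv(out_values, sep="\t")
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "group", "class"])
    if classes is None:
        meta = meta.drop(columns=["class"])
    meta.to_csv(out_meta, sep="\t", index=False)
    return frame


def _expression_truth(
    frame: pd.DataFrame, meta_groups: dict[str, str],
    classes: dict[str, str] | None = None,
) -> dict[str, pd.Series]:
    """Naive two-pass group-then-aggregate recomputation (oracle path)."""

    def agg(samples: list[str]) -> tuple[pd.Series, pd.Series]:
        by_group: dict[str, list[str]] = {}
        for s in samples:
            by_group.setdefault(meta_groups[s], []).append(s)
        means = pd.DataFrame(
            {g: frame[cols].mean(axis=1) for g, cols in by_group.items()}
        )
        return means.mean(axis=1), means.std(axis=1, ddof=1)

    if classes is None:
        return dict(zip(("avg", "sd"), agg(list(frame.columns))))
    out = {}
    for cls in ("treatment", "control"):
        cols = [s for s in frame.columns if classes[meta_groups[s]] == cls]
        avg, sd = agg(cols)
        out[f"avg_{cls}"] = avg
        out[f"sd_{cls}"] = sd
    return out


def simulate_raw_inputs(
    out_dir: str | Path, n_genes: int = 40, seed: int = 0
) -> RawInputs:
    """Write toy PPI/expression/annotation files plus a ground-truth sidecar.

    Files use the exact dialects the features module reads: STRING
    protein-links with a ``3702.`` species prefix, expression TSVs with
    sample-metadata companions, a GFF3 with gene/mRNA/exon records, and a
    (gene_id, domain_id) TSV.  ``truth.tsv`` holds the twelve feature
    values recomputed naively at generation time, for oracle tests.
    Gene 0 has constant expression everywhere (its SD features are 0).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = [f"AT1G{i + 1:05d}" for i in range(n_genes)]
    truth = pd.DataFrame(index=pd.Index(genes, name="gene_id"))

    # --- PPI ------------------------------------------------------------
    n_edges = n_genes * 4
    a = rng.integers(0, n_genes, size=n_edges)
    b = rng.integers(0, n_genes, size=n_edges)
    scores = rng.integers(150, 1000, size=n_edges)
    ppi_path = out / "ppi.tsv"
    with open(ppi_path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for i, j, s in zip(a, b, scores):
            if i == j:
                continue
            fh.write(f"3702.{genes[i]} 3702.{genes[j]} {s}\n")
            # STRING ships both edge directions; emit the mirror line too
            fh.write(f"3702.{genes[j]} 3702.{genes[i]} {s}\n")
    edge_frame = pd.DataFrame(
        {
            "protein_a": [genes[i] for i, j in zip(a, b) if i != j],
            "protein_b": [genes[j] for i, j in zip(a, b) if i != j],
            "combined_score": [int(s) for i, j, s in zip(a, b, scores) if i != j],
        }
    )
    network = PPINetwork(_normalize_edge_frame(edge_frame))
    high = network.edges[network.edges["combined_score"] >= 700]
    degree: dict[str, int] = {g: 0 for g in genes}
    for _, row in high.iterrows():
        degree[row["protein_a"]] += 1
        degree[row["protein_b"]] += 1
    truth["ppi count"] = pd.Series(degree)

    # --- expression -----------------------------------------------------
    tissue_frame = _write_expression(
        rng, genes, _TISSUES, reps=2,
        out_values=out / "expr_tissue.tsv", out_meta=out / "expr_tissue_samples.tsv",
        constant_gene=genes[0],
    )
    tissue_groups = {f"s{g_i:02d}_{r}": grp for g_i, grp in enumerate(_TISSUES) for r in range(2)}
    truth["SD exp. across tissues"] = _expression_truth(tissue_frame, tissue_groups)["sd"]

    accession_frame = _write_expression(
        rng, genes, _ACCESSIONS, reps=1,
        out_values=out / "expr_accession.tsv", out_meta=out / "expr_accession_samples.tsv",
        constant_gene=genes[0],
    )
    accession_groups = {f"s{g_i:02d}_0": grp for g_i, grp in enumerate(_ACCESSIONS)}
    avg_sd = _expression_truth(accession_frame, accession_groups)
    truth["avg exp. across accessions"] = avg_sd["avg"]
    truth["SD exp. across accessions"] = avg_sd["sd"]

    condition_groups = [f"exp{i}" for i in range(8)]
    classes = {g: ("treatment" if i < 4 else "control") for i, g in enumerate(condition_groups)}
    condition_frame = _write_expression(
        rng, genes, condition_groups, reps=2,
        out_values=out / "expr_condition.tsv", out_meta=out / "expr_condition_samples.tsv",
        classes=classes, constant_gene=genes[0],
    )
    cond_groups = {f"s{g_i:02d}_{r}": grp for g_i, grp in enumerate(condition_groups) for r in range(2)}
    cond_truth = _expression_truth(condition_frame, cond_groups, classes)
    truth["avg exp. across treatments"] = cond_truth["avg_treatment"]
    truth["avg exp. across controls"] = cond_truth["avg_control"]
    truth["SD exp. across treatments"] = cond_truth["sd_treatment"]
    truth["SD exp. across controls"] = cond_truth["sd_control"]

    # --- gene models + domains -----------------------------------------
    gff_path = out / "genes.gff3"
    introns, variants = {}, {}
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        pos = 1000
        for g in genes:
            n_tx = int(rng.integers(1, 4))
            exon_counts = [int(rng.integers(1, 7)) for _ in range(n_tx)]
            gene_len = max(exon_counts) * 400 + 200
            start, end = pos, pos + gene_len - 1
            fh.write(f"chr1\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={g}\n")
            best = None
            for t, n_ex in enumerate(exon_counts):
                tx_id = f"{g}.{t + 1}"
                fh.write(f"chr1\tsim\tmRNA\t{start}\t{end}\t.\t+\t.\tID={tx_id};Parent={g}\n")
                exon_len = 300
                total = 0
                for e in range(n_ex):
                    ex_start = start + e * 400
                    ex_end = ex_start + exon_len - 1
                    total += exon_len
                    fh.write(
                        f"chr1\tsim\texon\t{ex_start}\t{ex_end}\t.\t+\t.\t"
                        f"ID={tx_id}.exon{e + 1};Parent={tx_id}\n"
                    )
                key = (-total, tx_id)
                if best is None or key < best:
                    best = key
                    introns[g] = n_ex - 1
            variants[g] = n_tx
            pos = end + 500
    truth["introns"] = pd.Series(introns, dtype=float)
    truth["splice variants"] = pd.Series(variants, dtype=float)

    domain_pool = [f"PF{i:05d}" for i in range(15)]
    domain_rows = []
    total_dom, uniq_dom = {}, {}
    for g in genes:
        n_dom = int(rng.integers(0, 6))
        picks = [domain_pool[int(rng.integers(0, len(domain_pool)))] for _ in range(n_dom)]
        for d in picks:
            domain_rows.append((g, d))
        total_dom[g] = len(picks)
        uniq_dom[g] = len(set(picks))
    domains_path = out / "domains.tsv"
    pd.DataFrame(domain_rows, columns=["gene_id", "domain_id"]).to_csv(
        domains_path, sep="\t", index=False
    )
    truth["total domains"] = pd.Series(total_dom, dtype=float)
    truth["unique domains"] = pd.Series(uniq_dom, dtype=float)

    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    paths = {
        "ppi": ppi_path,
        "expr_tissue": out / "expr_tissue.tsv",
        "expr_tissue_meta": out / "expr_tissue_samples.tsv",
        "expr_accession": out / "expr_accession.tsv",
        "expr_accession_meta": out / "expr_accession_samples.tsv",
        "expr_condition": out / "expr_condition.tsv",
        "expr_condition_meta": out / "expr_condition_samples.tsv",
        "gff": gff_path,
        "domains": domains_path,
        "truth": truth_path,
    }
    return RawInputs(paths=paths, truth=truth, network=network)
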