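"""Gene-level feature construction from raw PPI, expression and annotation data.

Twelve features beyond the legacy polymorphism/annotation set are built here:

* ``ppi count`` — number of high-confidence protein-protein interaction
  partners (STRING combined score >= 700 by default);
* seven expression-variability features — mean and standard deviation of
  expression across tissues, accessions, and treatment/control conditions;
* four structural features — intron count of the representative transcript,
  splice-variant count, and total/unique protein-domain counts.

The module also provides the descriptive statistics used to characterise
features: pairwise Pearson correlations and Wilcoxon rank-sum comparisons
of positive (causal) versus negative genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from scipy import stats

from .table import FeatureTable, LabeledGeneSet

__all__ = [
    "PPINetwork",
    "ExpressionMatrix",
    "GeneStructureRecord",
    "read_string_edges",
    "ppi_count_feature",
    "read_expression_matrix",
    "expression_variability_features",
    "read_gene_structures",
    "read_domain_table",
    "structural_features",
    "assemble_feature_table",
    "feature_correlation_matrix",
    "compare_positive_vs_negative",
    "NEW_FEATURE_ORDER",
    "EXPRESSION_FEATURES",
]

logger = logging.getLogger(__name__)

#: Canonical order of the twelve new features when merged after legacy columns.
NEW_FEATURE_ORDER = [
    "ppi count",
    "SD exp. across tissues",
    "avg exp. across accessions",
    "SD exp. across accessions",
    "avg exp. across treatments",
    "avg exp. across controls",
    "SD exp. across treatments",
    "SD exp. across controls",
    "introns",
    "splice variants",
    "total domains",
    "unique domains",
]

EXPRESSION_FEATURES = {
    "tissue": ["SD exp. across tissues"],
    "accession": ["avg exp. across accessions", "SD exp. across accessions"],
    "condition": [
        "avg exp. across treatments",
        "avg exp. across controls",
        "SD exp. across treatments",
        "SD exp. across controls",
    ],
}


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network with confidence scores.

    Edges are stored canonically (a < b lexicographically) with duplicate
    undirected edges collapsed to their maximum combined score.  Scores
    follow the STRING convention: integers in [0, 1000].
    """

    edges: pd.DataFrame  # columns: protein_a, protein_b, combined_score

    def __post_init__(self) -> None:
        required = ["protein_a", "protein_b", "combined_score"]
        if list(self.edges.columns) != required:
            raise ValueError(f"edge frame must have columns {required}")
        scores = self.edges["combined_score"]
        if len(scores) and ((scores < 0) | (scores > 1000)).any():
            raise ValueError("combined scores must lie in [0, 1000]")
        if len(self.edges) and (self.edges["protein_a"] == self.edges["protein_b"]).any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self, min_score: int = 0) -> pd.Series:
        """Distinct-partner count per gene over edges with score >= min_score."""
        kept = self.edges[self.edges["combined_score"] >= min_score]
        counts = pd.concat([kept["protein_a"], kept["protein_b"]]).value_counts()
        return counts.sort_index()


def _normalize_edge_frame(frame: pd.DataFrame) -> pd.DataFrame:
    a = frame["protein_a"].to_numpy()
    b = frame["protein_b"].to_numpy()
    lo = np.where(a <= b, a, b)
    hi = np.where(a <= b, b, a)
    canon = pd.DataFrame(
        {"protein_a": lo, "protein_b": hi, "combined_score": frame["combined_score"].to_numpy()}
    )
    canon = canon[canon["protein_a"] != canon["protein_b"]]
    canon = (
        canon.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"]
        .max()
        .sort_values(["protein_a", "protein_b"], ignore_index=True)
    )
    return canon


def read_string_edges(
    path: str | Path,
    id_prefix_strip: str | None = None,
    alias: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Read a STRING protein-links file into a normalized :class:`PPINetwork`.

    The file is whitespace-separated with one header line and columns
    ``protein1 protein2 combined_score``.  Species prefixes such as
    ``3702.`` are stripped when ``id_prefix_strip`` is given; an explicit
    ``alias`` mapping (STRING id -> gene id) overrides prefix stripping.

    Duplicate undirected edges (a-b and b-a) are collapsed keeping the
    maximum score, and self-loops are dropped.
    """
    rows: list[tuple[str, str, int]] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, expected a header line")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 whitespace-separated columns, got {len(parts)}"
                )
            a, b, raw_score = parts
            try:
                score = int(raw_score)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer score {raw_score!r}") from None
            if not 0 <= score <= 1000:
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            rows.append((a, b, score))

    def map_id(pid: str) -> str:
        if alias is not None:
            return alias.get(pid, pid)
        if id_prefix_strip and pid.startswith(id_prefix_strip):
            return pid[len(id_prefix_strip):]
        return pid

    frame = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    if len(frame):
        frame["protein_a"] = frame["protein_a"].map(map_id)
        frame["protein_b"] = frame["protein_b"].map(map_id)
    return PPINetwork(_normalize_edge_frame(frame))


def ppi_count_feature(
    net: PPINetwork, genes: Sequence[str], min_score: int = 700
) -> pd.DataFrame:
    """Per-gene count of interaction partners with combined score >= min_score.

    Genes absent from the network get a count of 0 (absence is informative,
    not missing).  Low-confidence edges — score below the threshold — are
    discarded before counting.
    """
    if not 0 <= min_score <= 1000:
        raise ValueError("min_score must lie in [0, 1000]")
    degrees = net.degrees(min_score)
    counts = degrees.reindex(list(genes)).fillna(0).astype(float)
    return counts.to_frame("ppi count")


# ---------------------------------------------------------------------------
# Expression variability
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with per-sample group metadata.

    ``sample_meta`` is indexed by sample id and carries a ``group`` column
    (tissue name, accession name, experiment id, ...) and an optional
    ``class`` column in {treatment, control} used for the condition features.
    Values are nonnegative; NaN marks an unmeasured cell.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids in expression matrix")
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta must carry a 'group' column")
        meta_samples = set(self.sample_meta.index)
        missing = [s for s in self.values.columns if s not in meta_samples]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        if self.sample_meta["group"].isna().any():
            raise ValueError("every sample needs a group label")
        vals = self.values.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("expression values must be nonnegative")


def read_expression_matrix(
    values_path: str | Path, meta_path: str | Path
) -> ExpressionMatrix:
    """Read an expression TSV (gene ids in first column, sample ids in header)
    plus a sample-metadata TSV with columns sample_id, group[, class]."""
    values = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return ExpressionMatrix(values, meta)


def _group_means(expr: ExpressionMatrix, samples: pd.Index) -> pd.DataFrame:
    """Average samples sharing a group label; returns genes x groups."""
    groups = expr.sample_meta.loc[samples, "group"]
    return expr.values[samples].T.groupby(groups).mean().T


def expression_variability_features(
    expr: ExpressionMatrix,
    grouping: str,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Mean/SD-of-expression features across tissues, accessions or conditions.

    Samples sharing a group label are averaged first; the feature is then
    the mean and/or sample standard deviation (ddof=1) across group means.
    ``grouping`` selects the feature set:

    * ``tissue`` — one column, SD across tissue means;
    * ``accession`` — mean and SD across accession means;
    * ``condition`` — mean and SD computed separately over treatment and
      control samples (``class`` column required).

    With ``log2_transform`` the matrix is log2(x+1)-transformed first.
    A gene with no measurement in any contributing group comes out NaN
    (missing), to be flagged during table assembly.
    """
    if grouping not in EXPRESSION_FEATURES:
        raise ValueError(f"grouping must be one of {sorted(EXPRESSION_FEATURES)}")
    expr = ExpressionMatrix(
        np.log2(expr.values + 1.0) if log2_transform else expr.values,
        expr.sample_meta,
    )
    samples = expr.values.columns

    if grouping == "condition":
        if "class" not in expr.sample_meta.columns or expr.sample_meta.loc[samples, "class"].isna().any():
            raise ValueError("condition grouping requires a class label for every sample")
        bad = set(expr.sample_meta.loc[samples, "class"]) - {"treatment", "control"}
        if bad:
            raise ValueError(f"class labels must be treatment/control, got {sorted(bad)}")
        out = {}
        for cls, avg_name, sd_name in [
            ("treatment", "avg exp. across treatments", "SD exp. across treatments"),
            ("control", "avg exp. across controls", "SD exp. across controls"),
        ]:
            cls_samples = samples[(expr.sample_meta.loc[samples, "class"] == cls).to_numpy()]
            means = _group_means(expr, cls_samples)
            if means.shape[1] < 2:
                raise ValueError(
                    f"need >= 2 {cls} groups for an SD feature, found {means.shape[1]}"
                )
            out[avg_name] = means.mean(axis=1)
            out[sd_name] = means.std(axis=1, ddof=1)
        frame = pd.DataFrame(out)
        return frame[EXPRESSION_FEATURES["condition"]]

    means = _group_means(expr, samples)
    if means.shape[1] < 2:
        raise ValueError(f"need >= 2 {grouping} groups for an SD feature, found {means.shape[1]}")
    if grouping == "tissue":
        return means.std(axis=1, ddof=1).to_frame("SD exp. across tissues")
    return pd.DataFrame(
        {
            "avg exp. across accessions": means.mean(axis=1),
            "SD exp. across accessions": means.std(axis=1, ddof=1),
        }
    )


# ---------------------------------------------------------------------------
# Structural features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneStructureRecord:
    """Per-gene structure summary derived from the annotation.

    ``intron_count`` is exon count minus one on the representative
    transcript (the transcript with the greatest summed exon length, ties
    broken by smallest transcript id); ``transcript_count`` is the number
    of annotated splice variants.
    """

    gene_id: str
    transcript_count: int
    intron_count: int


def read_gene_structures(gff_path: str | Path) -> dict[str, GeneStructureRecord]:
    """Parse a GFF3 file into per-gene structure records.

    Expects gene -> mRNA -> exon feature hierarchy with ID/Parent links;
    a transcript with zero exons is a validation error.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records: dict[str, GeneStructureRecord] = {}
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        best: tuple[int, str] | None = None  # (-summed_exon_length, transcript_id)
        n_exons_best = 0
        for tx in transcripts:
            exons = list(db.children(tx, featuretype="exon"))
            if not exons:
                raise ValueError(f"transcript {tx.id} has no exons")
            length = sum(e.end - e.start + 1 for e in exons)
            key = (-length, tx.id)
            if best is None or key < best:
                best = key
                n_exons_best = len(exons)
        if not transcripts:
            raise ValueError(f"gene {gene.id} has no transcripts")
        records[gene.id] = GeneStructureRecord(
            gene_id=gene.id,
            transcript_count=len(transcripts),
            intron_count=n_exons_best - 1,
        )
    return records


def read_domain_table(path: str | Path) -> pd.DataFrame:
    """Read a domain-annotation TSV with columns gene_id, domain_id
    (extra columns ignored)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "domain_id"} <= set(frame.columns):
        raise ValueError("domain TSV needs columns gene_id and domain_id")
    return frame[["gene_id", "domain_id"]]


def structural_features(
    gene_models: Mapping[str, GeneStructureRecord],
    domains: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Four structure columns: introns, splice variants, total/unique domains.

    ``domains`` is a (gene_id, domain_id) frame where repeated rows encode
    multiple copies of a domain.  Genes missing from a source get NaN there
    and are flagged missing during assembly; domain rows for genes absent
    from the gene models are kept under their own id with a warning.
    """
    unknown = sorted(set(domains["gene_id"]) - set(gene_models))
    if unknown:
        logger.warning(
            "%d domain rows reference genes absent from the gene models (e.g. %s)",
            len(unknown), unknown[:3],
        )
    total = domains.groupby("gene_id")["domain_id"].size()
    unique = domains.groupby("gene_id")["domain_id"].nunique()
    if genes is None:
        genes = sorted(set(gene_models) | set(total.index))
    index = pd.Index(list(genes))
    structure = pd.DataFrame(
        {
            "introns": {g: r.intron_count for g, r in gene_models.items()},
            "splice variants": {g: r.transcript_count for g, r in gene_models.items()},
        },
        dtype=float,
    ).reindex(index)
    structure["total domains"] = total.reindex(index).astype(float)
    structure["unique domains"] = unique.reindex(index).astype(float)
    return structure


# ---------------------------------------------------------------------------
# Table assembly and descriptive statistics
# ---------------------------------------------------------------------------

def assemble_feature_table(
    legacy: FeatureTable,
    new_columns: Sequence[pd.DataFrame] | pd.DataFrame,
    impute: str = "zero",
) -> FeatureTable:
    """Outer-join new feature columns onto a legacy feature table.

    Column order is deterministic: legacy columns first, then new features
    in their canonical order (:data:`NEW_FEATURE_ORDER`) with any
    unrecognised new columns appended alphabetically.  Cells absent from a
    source are imputed (policy ``zero``: fill 0) and flagged in the missing
    mask.  Passing an empty new-column set returns the table unchanged, so
    assembly is idempotent under re-merge.
    """
    if impute != "zero":
        raise ValueError(f"unknown imputation policy {impute!r}")
    if isinstance(new_columns, pd.DataFrame):
        new_columns = [new_columns]
    if not new_columns:
        return FeatureTable(legacy.values.copy(), legacy.missing.copy())

    new = pd.concat(list(new_columns), axis=1, join="outer")
    if new.columns.has_duplicates:
        dups = new.columns[new.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature names among new columns: {dups}")
    clash = set(new.columns) & set(legacy.feature_names)
    if clash:
        raise ValueError(f"new feature names clash with legacy table: {sorted(clash)}")
    if not set(new.index) & set(legacy.gene_ids):
        raise ValueError("legacy table and new columns share no gene ids")

    order = [c for c in NEW_FEATURE_ORDER if c in new.columns]
    order += sorted(c for c in new.columns if c not in NEW_FEATURE_ORDER)
    new = new[order]

    gene_index = legacy.values.index.union(new.index, sort=False)
    # keep legacy gene order first, appended genes sorted for determinism
    appended = sorted(set(new.index) - set(legacy.gene_ids))
    gene_index = pd.Index(list(legacy.gene_ids) + appended)

    legacy_raw = legacy.raw.reindex(gene_index)
    merged = pd.concat([legacy_raw, new.reindex(gene_index)], axis=1)
    n_imputed = int(merged.isna().sum().sum())
    if n_imputed:
        logger.info("assemble_feature_table: imputed %d missing cells to 0", n_imputed)
    return FeatureTable(merged)


def feature_correlation_matrix(table: FeatureTable) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between features.

    Zero-variance features yield undefined (NaN) correlations rather than 0,
    so they can never join a correlation cluster spuriously.  The diagonal
    is set to 1 for every feature with any observed value.
    """
    corr = table.raw.corr(method="pearson", min_periods=2)
    observed = table.raw.notna().any()
    for name, seen in observed.items():
        if seen:
            corr.loc[name, name] = 1.0
    return corr


def compare_positive_vs_negative(
    table: FeatureTable, labels: LabeledGeneSet
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of each feature between classes.

    Returns per feature the class medians, the two-sided Mann-Whitney U
    statistic (tie-corrected normal approximation for p-values, exact for
    small tie-free samples) and whether the feature was testable (both
    classes had observed values).
    """
    labels.check_in_table(table)
    raw = table.raw
    pos_rows = raw.loc[sorted(labels.positives)]
    neg_rows = raw.loc[sorted(labels.negative_pool)]
    records = []
    for name in table.feature_names:
        pos = pos_rows[name].dropna().to_numpy()
        neg = neg_rows[name].dropna().to_numpy()
        if len(pos) == 0 or len(neg) == 0:
            records.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
        records.append(
            (name, float(np.median(pos)), float(np.median(neg)),
             float(res.statistic), float(res.pvalue), True)
        )
    return pd.DataFrame(
        records,
        columns=["feature", "median_pos", "median_neg", "statistic", "p_value", "testable"],
    ).set_index("feature")
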