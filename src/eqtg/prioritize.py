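"""Window-based prioritization of candidate causal genes.

A candidate eQTG is ranked against every gene within 1 Mbp on either side
of its span (a 2 Mbp hypothetical eQTL region).  The rank percent is the
percentage of window genes with a **strictly** higher mean causality
probability — a rank of 10% means 10% of genes in the region outscore the
candidate, so lower is better.  Recall at a cutoff k is the fraction of
candidates whose rank percent is below k.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .ensemble import EnsembleModel, predict_mean_probability
from .table import FeatureTable

__all__ = [
    "GeneLocus",
    "GeneAnnotation",
    "ValidationGene",
    "PrioritizationResult",
    "genes_in_window",
    "rank_percent",
    "recall_at",
    "prioritize_candidates",
    "read_candidates_tsv",
    "EVIDENCE_CLASSES",
]

EVIDENCE_CLASSES = frozenset(
    {"confirmed/strong-candidate", "hypothetical", "hypothetical-ortholog"}
)

DEFAULT_HALF_WIDTH = 1_000_000  # 1 Mbp either side -> 2 Mbp window


@dataclass(frozen=True)
class GeneLocus:
    """Genomic span of a gene (1-based, inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.gene_id}: coordinates must be positive")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start must not exceed end")


class GeneAnnotation:
    """Set of gene loci supporting window queries.

    Backed by a DataFrame (gene_id, chromosome, start, end, strand); the
    window query is a plain vectorized interval-overlap scan, which is
    ample at genome-annotation scale.
    """

    def __init__(self, loci: Iterable[GeneLocus]):
        records = [(l.gene_id, l.chromosome, l.start, l.end, l.strand) for l in loci]
        self.frame = pd.DataFrame(
            records, columns=["gene_id", "chromosome", "start", "end", "strand"]
        )
        if self.frame["gene_id"].duplicated().any():
            dups = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids in annotation: {dups.tolist()[:5]}")
        self.frame = self.frame.set_index("gene_id", drop=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    def locus(self, gene_id: str) -> GeneLocus:
        if gene_id not in self.frame.index:
            raise KeyError(f"gene {gene_id!r} absent from annotation")
        row = self.frame.loc[gene_id]
        return GeneLocus(row["gene_id"], row["chromosome"], int(row["start"]),
                         int(row["end"]), row["strand"])

    @classmethod
    def from_gff(cls, gff_path: str | Path) -> "GeneAnnotation":
        """Load gene records from a GFF3 file (gene id from the ID attribute)."""
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        loci = [
            GeneLocus(g.id, g.seqid, g.start, g.end, g.strand or "?")
            for g in db.features_of_type("gene")
        ]
        return cls(loci)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        loci = [
            GeneLocus(r.gene_id, r.chromosome, int(r.start), int(r.end),
                      getattr(r, "strand", "?"))
            for r in frame.itertuples()
        ]
        return cls(loci)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ValidationGene:
    """A literature-curated candidate eQTG with its evidence class."""

    gene_id: str
    evidence_class: str = "hypothetical"

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(
                f"evidence class {self.evidence_class!r} not in {sorted(EVIDENCE_CLASSES)}"
            )


@dataclass
class PrioritizationResult:
    """Scores and rank percents for one candidate's 2 Mbp window."""

    candidate: str
    window: pd.DataFrame  # gene_id, chromosome, start, end, mean_probability, rank_percent, is_candidate
    candidate_rank_percent: float


def genes_in_window(
    annotation: GeneAnnotation,
    candidate: str,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[str]:
    """Gene ids on the candidate's chromosome overlapping its +-half_width window.

    The window spans [candidate.start - half_width, candidate.end +
    half_width] clipped at position 1; any overlap with a gene's span
    (closed intervals) includes it, so a gene ending exactly at the window
    edge is in.  The candidate itself is always a member.
    """
    locus = annotation.locus(candidate)  # raises KeyError if absent
    lo = max(1, locus.start - half_width)
    hi = locus.end + half_width
    frame = annotation.frame
    mask = (
        (frame["chromosome"] == locus.chromosome)
        & (frame["end"] >= lo)
        & (frame["start"] <= hi)
    )
    return frame.loc[mask, "gene_id"].tolist()


def rank_percent(scores: Mapping[str, float] | pd.Series, candidate: str) -> float:
    """Percentage of window genes strictly outscoring the candidate.

    Ties do not count as higher, so a candidate with the unique maximum
    (or sharing it) scores 0%.  Always in [0, 100).
    """
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    if candidate not in scores.index:
        raise KeyError(f"candidate {candidate!r} absent from window scores")
    higher = int((scores > scores[candidate]).sum())
    return 100.0 * higher / len(scores)


def recall_at(
    results: Sequence[float], cutoffs: Sequence[float] = (5, 10, 20)
) -> dict[float, float]:
    """Fraction of candidates whose rank percent falls strictly below each cutoff.

    Strict comparison follows the rank definition: a candidate "within the
    top 20%" has fewer than 20% of window genes above it.  The mapping is
    monotone nondecreasing in the cutoff and equals 1.0 at cutoff 100.
    """
    ranks = list(results)
    if not ranks:
        raise ValueError("need at least one candidate rank")
    if not list(cutoffs):
        raise ValueError("cutoff list must be non-empty")
    return {float(c): sum(r < c for r in ranks) / len(ranks) for c in cutoffs}


def prioritize_candidates(
    model: EnsembleModel,
    table: FeatureTable,
    annotation: GeneAnnotation,
    candidates: Sequence[ValidationGene | str],
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[PrioritizationResult]:
    """Score and rank every candidate against its 2 Mbp genomic window.

    For each candidate the window genes are scored by ensemble mean
    probability and every window gene receives a rank percent; the result
    is deterministic given the fitted model.
    """
    results = []
    for cand in candidates:
        gene_id = cand.gene_id if isinstance(cand, ValidationGene) else cand
        window_ids = genes_in_window(annotation, gene_id, half_width)
        scores = predict_mean_probability(model, table, window_ids)
        ranks = {g: rank_percent(scores, g) for g in window_ids}
        rows = []
        for g in window_ids:
            locus = annotation.locus(g)
            rows.append(
                (g, locus.chromosome, locus.start, locus.end,
                 float(scores[g]), ranks[g], g == gene_id)
            )
        window = pd.DataFrame(
            rows,
            columns=["gene_id", "chromosome", "start", "end",
                     "mean_probability", "rank_percent", "is_candidate"],
        ).sort_values(["rank_percent", "gene_id"], ignore_index=True)
        results.append(
            PrioritizationResult(
                candidate=gene_id,
                window=window,
                candidate_rank_percent=ranks[gene_id],
            )
        )
    return results


def summarize_prioritization(
    results: Sequence[PrioritizationResult],
    candidates: Sequence[ValidationGene | str] | None = None,
    cutoffs: Sequence[float] = (5, 10, 20),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-candidate summary plus the recall table over rank cutoffs."""
    evidence = {}
    if candidates:
        for cand in candidates:
            if isinstance(cand, ValidationGene):
                evidence[cand.gene_id] = cand.evidence_class
    summary = pd.DataFrame(
        {
            "candidate": [r.candidate for r in results],
            "evidence_class": [evidence.get(r.candidate, "NA") for r in results],
            "rank_percent": [r.candidate_rank_percent for r in results],
            "window_size": [len(r.window) for r in results],
        }
    )
    recalls = recall_at([r.candidate_rank_percent for r in results], cutoffs)
    recall_frame = pd.DataFrame(
        {"cutoff_percent": list(recalls), "recall": list(recalls.values())}
    )
    return summary, recall_frame


def read_candidates_tsv(path: str | Path) -> list[ValidationGene]:
    """Read a candidate list TSV with columns gene_id[, evidence_class]."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in frame.columns:
        raise ValueError("candidate TSV needs a gene_id column")
    out = []
    for row in frame.itertuples():
        cls = getattr(row, "evidence_class", "hypothetical")
        out.append(ValidationGene(row.gene_id, cls if isinstance(cls, str) else "hypothetical"))
    return out
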