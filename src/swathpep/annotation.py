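"""HLA allele annotation of identified peptides.

A peptide is assigned to the allele with the lowest predicted IC50; the
annotation score is the ratio of the second-lowest to the lowest IC50 over
the donor's alleles. Peptides failing the score cutoff are curated into
supertype / HLA-C / non-annotated categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

STATUS_ANNOTATED = "annotated"
STATUS_SUPERTYPE = "supertype"
STATUS_HLA_C = "hla_c_binder"
STATUS_NON_ANNOTATED = "non_annotated"

STATUSES = (STATUS_ANNOTATED, STATUS_SUPERTYPE, STATUS_HLA_C, STATUS_NON_ANNOTATED)

DEFAULT_CUTOFF = 3.0
DEFAULT_SUPERTYPE_IC50 = 500.0


class PredictorError(RuntimeError):
    """Raised when the binding predictor fails for a peptide."""


@dataclass(frozen=True)
class AffinityVector:
    """Predicted IC50 (nM) of one peptide for each candidate allele."""

    peptide_sequence: str
    ic50_by_allele: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.ic50_by_allele:
            raise ValueError(
                f"empty allele map for peptide {self.peptide_sequence!r}"
            )
        for allele, ic50 in self.ic50_by_allele.items():
            if not allele:
                raise ValueError("allele names must be nonempty")
            if not (ic50 > 0) or not math.isfinite(ic50):
                raise ValueError(
                    f"IC50 for {allele} of {self.peptide_sequence!r} must be a "
                    f"positive finite number, got {ic50}"
                )


@dataclass
class AnnotationRecord:
    peptide_sequence: str
    best_allele: str
    best_ic50: float
    second_allele: str | None
    second_ic50: float | None
    score: float
    status: str
    ic50_by_allele: dict[str, float] = field(default_factory=dict)

    @property
    def display_score(self) -> int | float:
        """Score rounded to the nearest integer, as printed in reports."""
        return self.score if math.isinf(self.score) else round(self.score)


# A predictor maps (peptides, alleles) -> one AffinityVector per peptide.
Predictor = Callable[[Sequence[str], Sequence[str]], list[AffinityVector]]


def is_hla_c(allele: str) -> bool:
    name = allele.upper()
    if name.startswith("HLA-"):
        name = name[4:]
    return name.startswith("C")


def compute_annotation_score(affinities: AffinityVector) -> AnnotationRecord:
    """Rank alleles by predicted IC50 and compute the annotation score.

    The score is second-lowest IC50 / lowest IC50; a single-allele vector
    scores +inf (always annotatable), an exact tie scores 1 (never
    annotatable at any cutoff > 1). Status is left as non_annotated; use
    :func:`categorize` or :func:`annotate_peptides` to assign it.
    """
    items = sorted(affinities.ic50_by_allele.items(), key=lambda kv: (kv[1], kv[0]))
    best_allele, best_ic50 = items[0]
    if len(items) == 1:
        second_allele, second_ic50, score = None, None, math.inf
    else:
        second_allele, second_ic50 = items[1]
        score = second_ic50 / best_ic50
    return AnnotationRecord(
        peptide_sequence=affinities.peptide_sequence,
        best_allele=best_allele,
        best_ic50=best_ic50,
        second_allele=second_allele,
        second_ic50=second_ic50,
        score=score,
        status=STATUS_NON_ANNOTATED,
        ic50_by_allele=dict(affinities.ic50_by_allele),
    )


def categorize(
    record: AnnotationRecord,
    cutoff: float = DEFAULT_CUTOFF,
    supertype_ic50: float = DEFAULT_SUPERTYPE_IC50,
    include_hla_c: Iterable[str] = (),
) -> AnnotationRecord:
    """Assign the curation status in place and return the record.

    Precedence for score < cutoff: supertype, then HLA-C, then
    non-annotated. HLA-C alleles outside the whitelist are never annotation
    targets, whatever the score.
    """
    whitelist = {a.upper() for a in include_hla_c}
    best_is_c = is_hla_c(record.best_allele) and record.best_allele.upper() not in whitelist
    if record.score >= cutoff and not best_is_c:
        record.status = STATUS_ANNOTATED
    else:
        n_strong = sum(
            1 for v in record.ic50_by_allele.values() if v < supertype_ic50
        )
        if record.score < cutoff and n_strong >= 2:
            record.status = STATUS_SUPERTYPE
        elif best_is_c:
            record.status = STATUS_HLA_C
        else:
            record.status = STATUS_NON_ANNOTATED
    return record


def annotate_peptides(
    peptides: Sequence[str],
    donor_alleles: Sequence[str],
    predictor: Predictor,
    cutoff: float = DEFAULT_CUTOFF,
    supertype_ic50: float = DEFAULT_SUPERTYPE_IC50,
    include_hla_c: Iterable[str] = (),
) -> list[AnnotationRecord]:
    """Predict affinities for every peptide and curate each into a category."""
    if not donor_alleles:
        raise ValueError("donor_alleles must be nonempty")
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    try:
        vectors = predictor(list(peptides), list(donor_alleles))
    except Exception as exc:  # noqa: BLE001 - rewrap with peptide context
        raise PredictorError(f"predictor failed on batch: {exc}") from exc
    if len(vectors) != len(peptides):
        raise PredictorError(
            f"predictor returned {len(vectors)} vectors for {len(peptides)} peptides"
        )
    records = []
    for peptide, vec in zip(peptides, vectors):
        if vec.peptide_sequence != peptide:
            raise PredictorError(
                f"predictor returned vector for {vec.peptide_sequence!r}, "
                f"expected {peptide!r}"
            )
        for allele in donor_alleles:
            if allele not in vec.ic50_by_allele:
                raise PredictorError(
                    f"predictor missing allele {allele} for peptide {peptide!r}"
                )
        rec = compute_annotation_score(vec)
        records.append(categorize(rec, cutoff, supertype_ic50, include_hla_c))
    return records


@dataclass
class AlleleSummary:
    allele: str
    n_peptides: int
    ic50_cdf: list[tuple[float, float]]
    ic50_at_q95: float
    frac_below_500nM: float


def allele_summary(
    records: Iterable[AnnotationRecord], allele: str
) -> AlleleSummary | None:
    """Empirical best-IC50 distribution over peptides annotated to one allele.

    Returns None when no annotated peptide exists for the allele.
    """
    ic50s = np.sort(
        np.array(
            [
                r.best_ic50
                for r in records
                if r.status == STATUS_ANNOTATED and r.best_allele == allele
            ]
        )
    )
    n = ic50s.size
    if n == 0:
        return None
    cumfrac = np.arange(1, n + 1) / n
    q95 = float(ic50s[np.searchsorted(cumfrac, 0.95, side="left")])
    return AlleleSummary(
        allele=allele,
        n_peptides=int(n),
        ic50_cdf=list(zip(ic50s.tolist(), cumfrac.tolist())),
        ic50_at_q95=q95,
        frac_below_500nM=float(np.mean(ic50s < 500.0)),
    )


PERCENTILE_BINS = ("top1", "top5", "top10", "below90")


def source_protein_rank(
    peptide: str,
    protein: str,
    allele: str,
    predictor: Predictor,
) -> str:
    """Percentile bin of a peptide's IC50 among all same-length tiles of its
    source protein (rank 1 = strongest binder)."""
    if peptide not in protein:
        raise ValueError(f"peptide {peptide!r} not found in protein")
    k = len(peptide)
    tiles = [protein[i : i + k] for i in range(len(protein) - k + 1)]
    vectors = predictor(tiles, [allele])
    ic50s = [v.ic50_by_allele[allele] for v in vectors]
    query_ic50 = ic50s[tiles.index(peptide)]
    rank = 1 + sum(1 for v in ic50s if v < query_ic50)
    frac = rank / len(tiles)
    # the strongest tile is top1 by definition, whatever the tile count
    if rank == 1 or frac <= 0.01:
        return "top1"
    if frac <= 0.05:
        return "top5"
    if frac <= 0.10:
        return "top10"
    return "below90"


def build_heatmap_matrix(
    records: Sequence[AnnotationRecord],
    alleles: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """Peptide x allele matrix of -log10(IC50 nM).

    Rows are grouped by assigned allele (in the order of ``alleles``, with
    non-annotated peptides in a trailing block) and sorted within each block
    by ascending best IC50. Returns the matrix and the row peptide order.
    """
    if not records:
        raise ValueError("need at least one annotation record")
    blocks: list[AnnotationRecord] = []
    for allele in alleles:
        group = [
            r for r in records if r.status == STATUS_ANNOTATED and r.best_allele == allele
        ]
        blocks.extend(sorted(group, key=lambda r: (r.best_ic50, r.peptide_sequence)))
    rest = [r for r in records if r.status != STATUS_ANNOTATED]
    blocks.extend(sorted(rest, key=lambda r: (r.best_ic50, r.peptide_sequence)))
    matrix = np.array(
        [[-math.log10(r.ic50_by_allele[a]) for a in alleles] for r in blocks]
    )
    return matrix, [r.peptide_sequence for r in blocks]


def status_counts(records: Iterable[AnnotationRecord]) -> dict[str, int]:
    counts = {s: 0 for s in STATUSES}
    for r in records:
        counts[r.status] += 1
    return counts
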