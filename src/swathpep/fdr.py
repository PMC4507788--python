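"""Peptide-level target-decoy FDR and the annotation-corrected FDR (cFDR)."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import STATUS_ANNOTATED, AnnotationRecord


@dataclass(frozen=True)
class ScoredPeptide:
    """One identified peptide with its combined search probability."""

    sequence: str
    probability: float
    is_decoy: bool
    charge: int = 2
    sample_id: str = ""
    rt_seconds: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"probability must be in [0, 1], got {self.probability} "
                f"for {self.sequence!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FdrResult:
    threshold_probability: float
    n_targets: int
    n_decoys: int
    fdr: float


def _estimate(n_targets: int, n_decoys: int) -> float:
    # Simple decoys/targets estimator; no +1 and no pi0 correction.
    if n_targets == 0:
        return 0.0 if n_decoys == 0 else 1.0
    return n_decoys / n_targets


def filter_peptides(
    peptides: Iterable[ScoredPeptide],
    min_probability: float = 0.7,
    min_len: int = 8,
    max_len: int = 12,
) -> list[ScoredPeptide]:
    """Probability and length filter; decoys are kept for FDR accounting."""
    return [
        p
        for p in peptides
        if p.probability >= min_probability and min_len <= p.length <= max_len
    ]


def collapse_psms(peptides: Iterable[ScoredPeptide]) -> list[ScoredPeptide]:
    """Collapse replicate rows to peptide level: best probability per
    distinct (sequence, charge)."""
    best: dict[tuple[str, int], ScoredPeptide] = {}
    for p in peptides:
        key = (p.sequence, p.charge)
        if key not in best or p.probability > best[key].probability:
            best[key] = p
    return list(best.values())


def fdr_threshold(
    peptides: Sequence[ScoredPeptide], target_fdr: float
) -> FdrResult:
    """Lowest probability threshold with decoys/targets <= target_fdr.

    Thresholds are scanned at observed probability values; among qualifying
    thresholds the one maximizing the target count is returned (ties broken
    by the lower threshold, which never reduces the count).
    """
    if not 0 < target_fdr < 1:
        raise ValueError(f"target_fdr must be in (0, 1), got {target_fdr}")
    ranked = sorted(peptides, key=lambda p: -p.probability)
    best: FdrResult | None = None
    n_targets = n_decoys = 0
    for i, p in enumerate(ranked):
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        # only evaluate at the last row of each distinct probability value
        if i + 1 < len(ranked) and ranked[i + 1].probability == p.probability:
            continue
        fdr = _estimate(n_targets, n_decoys)
        if fdr <= target_fdr and (best is None or n_targets >= best.n_targets):
            best = FdrResult(p.probability, n_targets, n_decoys, fdr)
    if best is None:
        warnings.warn(
            f"no threshold achieves FDR <= {target_fdr}; returning empty result",
            stacklevel=2,
        )
        return FdrResult(math.inf, 0, 0, 0.0)
    return best


def apply_threshold(
    peptides: Iterable[ScoredPeptide], threshold_probability: float
) -> list[ScoredPeptide]:
    return [p for p in peptides if p.probability >= threshold_probability]


def corrected_fdr(
    peptides_passing: Sequence[ScoredPeptide],
    annotation: Mapping[str, AnnotationRecord] | Sequence[AnnotationRecord],
) -> FdrResult:
    """cFDR after removing non-annotated peptides from targets and decoys.

    Both target and decoy sequences must appear in ``annotation`` (decoys are
    run through the same predictor); a missing peptide is an error.
    """
    if not isinstance(annotation, Mapping):
        annotation = {r.peptide_sequence: r for r in annotation}
    n_targets = n_decoys = 0
    for p in peptides_passing:
        rec = annotation.get(p.sequence)
        if rec is None:
            raise KeyError(f"no annotation record for peptide {p.sequence!r}")
        if rec.status != STATUS_ANNOTATED:
            continue
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
    return FdrResult(
        threshold_probability=min(
            (p.probability for p in peptides_passing), default=math.inf
        ),
        n_targets=n_targets,
        n_decoys=n_decoys,
        fdr=_estimate(n_targets, n_decoys),
    )
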