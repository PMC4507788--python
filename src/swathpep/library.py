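"""Consensus spectral libraries and SWATH assay generation.

Covers: iRT normalization against landmark peptides, consensus spectrum
construction from replicate identifications, transition selection under the
b/y, charge 1-2, 350-2000 Th, 6-transition constraints, shuffle-decoy assay
generation and library merging.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .masses import fragment_mz, precursor_mz
from .windows import WindowScheme, assign_precursor_window

logger = logging.getLogger(__name__)

DEFAULT_MZ_RANGE = (350.0, 2000.0)
DEFAULT_MIN_TRANSITIONS = 6
DEFAULT_MAX_TRANSITIONS = 6
DEFAULT_MATCH_TOLERANCE = 0.05


@dataclass
class PeakSpectrum:
    """One fragment spectrum of an identified peptide ion."""

    peptide_sequence: str
    precursor_charge: int
    precursor_mz: float
    peaks: list[tuple[float, float]]
    rt_seconds: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        expected = precursor_mz(self.peptide_sequence, self.precursor_charge)
        if abs(expected - self.precursor_mz) > 0.1:
            raise ValueError(
                f"precursor m/z {self.precursor_mz:.4f} inconsistent with "
                f"{self.peptide_sequence}/{self.precursor_charge} "
                f"(expected {expected:.4f})"
            )
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be nonnegative")
        self.peaks = sorted(self.peaks)


@dataclass
class ConsensusEntry:
    peptide_sequence: str
    precursor_charge: int
    precursor_mz: float
    consensus_peaks: list[tuple[float, float]]
    irt: float
    allele: str = ""
    n_replicates: int = 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.peptide_sequence, self.precursor_charge)

    @property
    def total_intensity(self) -> float:
        return sum(i for _, i in self.consensus_peaks)


@dataclass(frozen=True)
class TransitionAssay:
    peptide_sequence: str
    precursor_mz: float
    precursor_charge: int
    fragment_mz: float
    fragment_type: str
    fragment_ordinal: int
    fragment_charge: int
    library_intensity: float
    irt: float
    is_decoy: bool
    transition_group_id: str

    @property
    def transition_name(self) -> str:
        return (
            f"{self.fragment_type}{self.fragment_ordinal}^{self.fragment_charge}"
            f"_{self.transition_group_id}"
        )


@dataclass(frozen=True)
class IrtModel:
    """Linear map from gradient retention time (s) to iRT units."""

    slope: float
    intercept: float
    r_squared: float
    n_landmarks: int

    def rt_to_irt(self, rt_seconds: float) -> float:
        return self.slope * rt_seconds + self.intercept

    def irt_to_rt(self, irt: float) -> float:
        return (irt - self.intercept) / self.slope


def fit_irt(
    observed: Sequence[tuple[str, float]],
    reference: Sequence[tuple[str, float]],
) -> IrtModel:
    """Least-squares line mapping observed landmark RTs onto reference iRTs."""
    ref = dict(reference)
    common = [(rt, ref[seq]) for seq, rt in observed if seq in ref]
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 common landmark peptides, got {len(common)}"
        )
    x = np.array([rt for rt, _ in common])
    y = np.array([irt for _, irt in common])
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError(
            f"fitted slope {fit.slope:.4g} is not positive (gradient reversed?)"
        )
    return IrtModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_landmarks=len(common),
    )


def build_consensus(
    replicates: Sequence[PeakSpectrum],
    irt_model: IrtModel | None = None,
    allele: str = "",
    match_tolerance_th: float = DEFAULT_MATCH_TOLERANCE,
) -> ConsensusEntry:
    """Aggregate replicate spectra of one peptide ion into a consensus.

    Peaks are clustered across replicates within ``match_tolerance_th``;
    consensus m/z and intensity are the per-cluster medians. With >= 3
    replicates, peaks present in fewer than half of them are dropped.
    """
    if not replicates:
        raise ValueError("need at least one replicate spectrum")
    keys = {(r.peptide_sequence, r.precursor_charge) for r in replicates}
    if len(keys) > 1:
        raise ValueError(f"replicates mix peptide ions: {sorted(keys)}")
    n = len(replicates)

    pool = sorted(
        (mz, intensity, idx)
        for idx, spec in enumerate(replicates)
        for mz, intensity in spec.peaks
    )
    clusters: list[list[tuple[float, float, int]]] = []
    for peak in pool:
        if clusters and peak[0] - clusters[-1][0][0] <= match_tolerance_th:
            clusters[-1].append(peak)
        else:
            clusters.append([peak])

    consensus_peaks = []
    for cluster in clusters:
        reps = {idx for _, _, idx in cluster}
        if n >= 3 and len(reps) / n < 0.5:
            continue
        mzs = [mz for mz, _, _ in cluster]
        intensities = [i for _, i, _ in cluster]
        consensus_peaks.append(
            (float(np.median(mzs)), float(np.median(intensities)))
        )

    rts = [r.rt_seconds for r in replicates]
    irts = [irt_model.rt_to_irt(rt) for rt in rts] if irt_model else rts
    first = replicates[0]
    return ConsensusEntry(
        peptide_sequence=first.peptide_sequence,
        precursor_charge=first.precursor_charge,
        precursor_mz=precursor_mz(first.peptide_sequence, first.precursor_charge),
        consensus_peaks=sorted(consensus_peaks),
        irt=float(np.median(irts)),
        allele=allele,
        n_replicates=n,
    )


def theoretical_fragments(
    sequence: str,
    ion_types: Iterable[str] = ("b", "y"),
    fragment_charges: Iterable[int] = (1, 2),
) -> list[tuple[str, int, int, float]]:
    """All (type, ordinal, charge, m/z) b/y fragments of a peptide."""
    out = []
    for ion_type in ion_types:
        for ordinal in range(1, len(sequence)):
            for charge in fragment_charges:
                out.append(
                    (ion_type, ordinal, charge,
                     fragment_mz(sequence, ion_type, ordinal, charge))
                )
    return out


def select_transitions(
    entry: ConsensusEntry,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    ion_types: Iterable[str] = ("b", "y"),
    fragment_charges: Iterable[int] = (1, 2),
    min_transitions: int = DEFAULT_MIN_TRANSITIONS,
    max_transitions: int = DEFAULT_MAX_TRANSITIONS,
    match_tolerance_th: float = DEFAULT_MATCH_TOLERANCE,
    excluded_windows: WindowScheme | None = None,
) -> list[TransitionAssay]:
    """Pick the most intense annotatable fragments of a consensus entry.

    Consensus peaks are annotated against theoretical b/y m/z within the
    match tolerance; fragments outside ``mz_range`` or inside the precursor's
    own isolation window (when a scheme is given) are discarded. Returns []
    when fewer than ``min_transitions`` fragments qualify — the peptide is
    then dropped from the library.
    """
    if not entry.consensus_peaks:
        raise ValueError("consensus entry has no peaks")
    own_window = (
        assign_precursor_window(entry.precursor_mz, excluded_windows)
        if excluded_windows is not None
        else None
    )
    peak_mz = np.array([mz for mz, _ in entry.consensus_peaks])
    peak_int = np.array([i for _, i in entry.consensus_peaks])

    candidates = []
    for ion_type, ordinal, charge, mz in theoretical_fragments(
        entry.peptide_sequence, ion_types, fragment_charges
    ):
        if not mz_range[0] <= mz <= mz_range[1]:
            continue
        if own_window is not None:
            core = excluded_windows.core(own_window)
            if core[0] <= mz < core[1]:
                continue
        matched = np.abs(peak_mz - mz) <= match_tolerance_th
        if not matched.any():
            continue
        intensity = float(peak_int[matched].max())
        candidates.append((ion_type, ordinal, charge, mz, intensity))

    candidates.sort(key=lambda c: (-c[4], c[3]))
    if len(candidates) < min_transitions:
        return []
    group_id = f"{entry.peptide_sequence}/{entry.precursor_charge}"
    return [
        TransitionAssay(
            peptide_sequence=entry.peptide_sequence,
            precursor_mz=entry.precursor_mz,
            precursor_charge=entry.precursor_charge,
            fragment_mz=mz,
            fragment_type=ion_type,
            fragment_ordinal=ordinal,
            fragment_charge=charge,
            library_intensity=intensity,
            irt=entry.irt,
            is_decoy=False,
            transition_group_id=group_id,
        )
        for ion_type, ordinal, charge, mz, intensity in
        candidates[:max_transitions]
    ]


def build_assay_library(
    entries: Iterable[ConsensusEntry], **kwargs
) -> tuple[list[TransitionAssay], list[str]]:
    """Select transitions for every entry; returns (assays, rejected ids)."""
    assays: list[TransitionAssay] = []
    rejects: list[str] = []
    for entry in entries:
        selected = select_transitions(entry, **kwargs)
        if selected:
            assays.extend(selected)
        else:
            rejects.append(f"{entry.peptide_sequence}/{entry.precursor_charge}")
    return assays, rejects


def _shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle all residues except the C-terminal one."""
    head = list(sequence[:-1])
    rng.shuffle(head)
    return "".join(head) + sequence[-1]


def _peptide_rng(seed: int, sequence: str) -> np.random.Generator:
    # per-peptide stream: decoys are independent of library ordering
    return np.random.default_rng(
        (seed & 0xFFFFFFFF) ^ zlib.crc32(sequence.encode())
    )


def generate_decoy_assays(
    assays: Sequence[TransitionAssay],
    method: str = "shuffle",
    similarity_threshold_th: float = 0.05,
    identity_threshold: float = 1.0,
    exclude_similar: bool = True,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    seed: int = 0,
    max_retries: int = 10,
) -> list[TransitionAssay]:
    """Sequence-shuffle (or reverse) decoy assays mirroring the targets.

    Each target group's sequence is permuted with the C-terminal residue
    fixed; fragment m/z are recomputed on the decoy sequence for the same ion
    series. Decoys identical to their target, too similar in fragment space
    (every decoy fragment within ``similarity_threshold_th`` of a target
    fragment), or leaving ``mz_range`` are re-shuffled and finally dropped.
    """
    if not assays:
        raise ValueError("assays must be nonempty")
    if method not in ("shuffle", "reverse"):
        raise ValueError(f"unknown decoy method {method!r}")

    groups: dict[str, list[TransitionAssay]] = {}
    for a in assays:
        if not a.is_decoy:
            groups.setdefault(a.transition_group_id, []).append(a)

    target_sequences = {g[0].peptide_sequence for g in groups.values()}
    decoys: list[TransitionAssay] = []
    for group_id, members in groups.items():
        target = members[0].peptide_sequence
        rng = _peptide_rng(seed, target)
        attempts = 1 if method == "reverse" else max_retries
        emitted = False
        for _ in range(attempts):
            if method == "reverse":
                decoy_seq = target[-2::-1] + target[-1]
            else:
                decoy_seq = _shuffle_sequence(target, rng)
            if decoy_seq in target_sequences:
                continue
            identity = sum(a == b for a, b in zip(decoy_seq, target)) / len(target)
            if identity > identity_threshold:
                continue
            decoy_mz = [
                fragment_mz(decoy_seq, m.fragment_type, m.fragment_ordinal,
                            m.fragment_charge)
                for m in members
            ]
            if any(not mz_range[0] <= mz <= mz_range[1] for mz in decoy_mz):
                continue
            if exclude_similar:
                target_mz = [m.fragment_mz for m in members]
                all_close = all(
                    any(abs(d - t) <= similarity_threshold_th for t in target_mz)
                    for d in decoy_mz
                )
                if all_close:
                    continue
            for m, mz in zip(members, decoy_mz):
                decoys.append(
                    replace(
                        m,
                        peptide_sequence=decoy_seq,
                        fragment_mz=mz,
                        is_decoy=True,
                        transition_group_id=f"DECOY_{group_id}",
                    )
                )
            emitted = True
            break
        if not emitted:
            logger.warning(
                "no valid decoy for %s after %d attempts; excluded",
                group_id, attempts,
            )
    return decoys


def merge_libraries(
    libraries: Iterable[Iterable[ConsensusEntry]],
) -> list[ConsensusEntry]:
    """Union by (sequence, charge); collisions keep the entry with more
    replicates, ties broken by higher total intensity."""
    merged: dict[tuple[str, int], ConsensusEntry] = {}
    for library in libraries:
        for entry in library:
            incumbent = merged.get(entry.key)
            if incumbent is None:
                merged[entry.key] = entry
            elif (entry.n_replicates, entry.total_intensity) > (
                incumbent.n_replicates, incumbent.total_intensity
            ):
                merged[entry.key] = entry
    return list(merged.values())
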