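"""Readers and writers for every interchange file, plus run configuration.

Dialects
--------
identifications : TSV, columns sample_id, sequence, charge, probability,
                  is_decoy, rt_seconds
typing          : TSV, columns sample_id, alleles (comma-separated)
iRT reference   : TSV, columns sequence, irt
assay library   : OpenSWATH-style transition TSV (column names bit-exact)
spectral library: sptxt-style text blocks
windows         : two-column swaths.txt (see swathpep.windows)

All writers emit LF; readers tolerate CRLF. Numeric precision on write:
m/z 1e-4, intensity 1e-2, iRT 1e-4.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

from .fdr import ScoredPeptide
from .library import ConsensusEntry, TransitionAssay


class SchemaError(ValueError):
    """A file does not match its documented dialect."""


IDENTIFICATION_COLUMNS = (
    "sample_id", "sequence", "charge", "probability", "is_decoy", "rt_seconds",
)

ASSAY_COLUMNS = (
    "PrecursorMz", "ProductMz", "Tr_recalibrated", "transition_name",
    "LibraryIntensity", "transition_group_id", "decoy", "PeptideSequence",
    "ProteinName", "FragmentType", "FragmentCharge", "FragmentSeriesNumber",
)


def _open_reader(path: str | Path):
    return open(path, newline="")


def _check_header(path, header: Sequence[str], expected: Sequence[str]) -> None:
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; header={header}")


def read_identifications(path: str | Path) -> list[ScoredPeptide]:
    peptides = []
    with _open_reader(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames or [], IDENTIFICATION_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            try:
                peptides.append(
                    ScoredPeptide(
                        sequence=row["sequence"].upper(),
                        probability=float(row["probability"]),
                        is_decoy=_parse_bool(row["is_decoy"]),
                        charge=int(row["charge"]),
                        sample_id=row["sample_id"],
                        rt_seconds=float(row["rt_seconds"]),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise SchemaError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return peptides


def write_identifications(peptides: Iterable[ScoredPeptide], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write("\t".join(IDENTIFICATION_COLUMNS) + "\n")
        for p in peptides:
            handle.write(
                f"{p.sample_id}\t{p.sequence}\t{p.charge}\t{p.probability:.6f}"
                f"\t{int(p.is_decoy)}\t{p.rt_seconds:.3f}\n"
            )


def _parse_bool(text: str) -> bool:
    value = text.strip().lower()
    if value in ("1", "true", "yes"):
        return True
    if value in ("0", "false", "no"):
        return False
    raise ValueError(f"not a boolean flag: {text!r}")


def read_typing(path: str | Path) -> dict[str, list[str]]:
    """sample_id -> allele list."""
    typing = {}
    with _open_reader(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames or [], ("sample_id", "alleles"))
        for lineno, row in enumerate(reader, start=2):
            alleles = [a.strip() for a in row["alleles"].split(",") if a.strip()]
            if not alleles:
                raise SchemaError(f"{path}:{lineno}: empty allele list")
            typing[row["sample_id"]] = alleles
    return typing


def write_typing(typing: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write("sample_id\talleles\n")
        for sample_id, alleles in typing.items():
            handle.write(f"{sample_id}\t{','.join(alleles)}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein id -> uppercase sequence (wrapped lines concatenated)."""
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(proteins: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as handle:
        for name, seq in proteins.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_irt_reference(path: str | Path) -> list[tuple[str, float]]:
    reference = []
    with _open_reader(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames or [], ("sequence", "irt"))
        for lineno, row in enumerate(reader, start=2):
            try:
                reference.append((row["sequence"].upper(), float(row["irt"])))
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return reference


def write_irt_reference(reference: Iterable[tuple[str, float]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write("sequence\tirt\n")
        for seq, irt in reference:
            handle.write(f"{seq}\t{irt:.4f}\n")


def write_assay_tsv(assays: Iterable[TransitionAssay], path: str | Path) -> None:
    seen: set[str] = set()
    with open(path, "w", newline="\n") as handle:
        handle.write("\t".join(ASSAY_COLUMNS) + "\n")
        for a in assays:
            name = a.transition_name
            if name in seen:
                raise SchemaError(f"duplicate transition_name {name!r}")
            seen.add(name)
            handle.write(
                f"{a.precursor_mz:.4f}\t{a.fragment_mz:.4f}\t{a.irt:.4f}"
                f"\t{name}\t{a.library_intensity:.2f}\t{a.transition_group_id}"
                f"\t{int(a.is_decoy)}\t{a.peptide_sequence}\tsynthetic"
                f"\t{a.fragment_type}\t{a.fragment_charge}\t{a.fragment_ordinal}\n"
            )


def read_assay_tsv(path: str | Path) -> list[TransitionAssay]:
    assays = []
    seen: set[str] = set()
    with _open_reader(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_header(path, reader.fieldnames or [], ASSAY_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            try:
                name = row["transition_name"]
                if name in seen:
                    raise ValueError(f"duplicate transition_name {name!r}")
                seen.add(name)
                assays.append(
                    TransitionAssay(
                        peptide_sequence=row["PeptideSequence"],
                        precursor_mz=float(row["PrecursorMz"]),
                        precursor_charge=int(row["transition_group_id"].rsplit("/", 1)[1]),
                        fragment_mz=float(row["ProductMz"]),
                        fragment_type=row["FragmentType"],
                        fragment_ordinal=int(row["FragmentSeriesNumber"]),
                        fragment_charge=int(row["FragmentCharge"]),
                        library_intensity=float(row["LibraryIntensity"]),
                        irt=float(row["Tr_recalibrated"]),
                        is_decoy=_parse_bool(row["decoy"]),
                        transition_group_id=row["transition_group_id"],
                    )
                )
            except (ValueError, KeyError) as exc:
                raise SchemaError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return assays


def write_spectral_library(entries: Iterable[ConsensusEntry], path: str | Path) -> None:
    """sptxt-style text blocks: Name, PrecursorMZ, Charge, iRT, Allele,
    NumReplicates, NumPeaks, then one "mz<TAB>intensity" line per peak."""
    with open(path, "w", newline="\n") as handle:
        for e in entries:
            handle.write(f"Name: {e.peptide_sequence}/{e.precursor_charge}\n")
            handle.write(f"PrecursorMZ: {e.precursor_mz:.4f}\n")
            handle.write(f"Charge: {e.precursor_charge}\n")
            handle.write(f"iRT: {e.irt:.4f}\n")
            handle.write(f"Allele: {e.allele}\n")
            handle.write(f"NumReplicates: {e.n_replicates}\n")
            handle.write(f"NumPeaks: {len(e.consensus_peaks)}\n")
            for mz, intensity in e.consensus_peaks:
                handle.write(f"{mz:.4f}\t{intensity:.2f}\n")
            handle.write("\n")


def read_spectral_library(path: str | Path) -> list[ConsensusEntry]:
    entries = []
    block: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    expected_peaks = 0

    def flush() -> None:
        if not block:
            return
        seq, charge = block["Name"].rsplit("/", 1)
        if len(peaks) != expected_peaks:
            raise SchemaError(
                f"{path}: entry {block['Name']} declares {expected_peaks} "
                f"peaks but has {len(peaks)}"
            )
        entries.append(
            ConsensusEntry(
                peptide_sequence=seq,
                precursor_charge=int(charge),
                precursor_mz=float(block["PrecursorMZ"]),
                consensus_peaks=list(peaks),
                irt=float(block["iRT"]),
                allele=block.get("Allele", ""),
                n_replicates=int(block.get("NumReplicates", 1)),
            )
        )

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush()
            block, peaks, expected_peaks = {}, [], 0
            continue
        if ":" in line and not line[0].isdigit():
            key, value = line.split(":", 1)
            block[key] = value.strip()
            if key == "NumPeaks":
                expected_peaks = int(value)
        else:
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: malformed peak line {raw!r}")
            peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return entries


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")


@dataclasses.dataclass
class RunConfig:
    """All pipeline tunables with their defaults."""

    cutoff: float = 3.0
    supertype_ic50: float = 500.0
    include_hla_c: tuple[str, ...] = ()
    min_probability: float = 0.7
    min_length: int = 8
    max_length: int = 12
    fdr_targets: tuple[float, ...] = (0.01, 0.05)
    mz_range: tuple[float, float] = (350.0, 2000.0)
    min_transitions: int = 6
    max_transitions: int = 6
    match_tolerance_th: float = 0.05
    decoy_method: str = "shuffle"
    similarity_threshold_th: float = 0.05
    identity_threshold: float = 1.0
    window_range: tuple[float, float] = (400.0, 1200.0)
    window_width: float = 25.0
    window_overlap: float = 1.0
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        coerced = {}
        for key, value in data.items():
            if isinstance(value, list):
                value = tuple(value)
            coerced[key] = value
        return cls(**coerced)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in out.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
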