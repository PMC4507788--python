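"""End-to-end orchestration: fixtures -> filter/FDR -> annotate -> cFDR ->
consensus library -> assays -> decoys -> windows -> reports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .annotation import (
    STATUS_ANNOTATED,
    annotate_peptides,
    status_counts,
)
from .fdr import (
    apply_threshold,
    collapse_psms,
    corrected_fdr,
    fdr_threshold,
    filter_peptides,
)
from .fixtures import (
    IRT_LANDMARKS,
    FixtureSpec,
    MockPredictor,
    generate_identifications,
    generate_source_protein,
    generate_spectra,
)
from .io_formats import (
    RunConfig,
    read_identifications,
    read_irt_reference,
    read_typing,
    write_assay_tsv,
    write_fasta,
    write_identifications,
    write_irt_reference,
    write_report,
    write_spectral_library,
    write_typing,
)
from .library import (
    build_assay_library,
    build_consensus,
    fit_irt,
    generate_decoy_assays,
    merge_libraries,
)
from .windows import make_window_scheme, write_window_file

STAGES = (
    "filter", "fdr", "annotate", "cfdr", "consensus", "assays", "decoys",
    "windows", "report",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def write_sample_dir(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Materialize a complete synthetic sample directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, truth = generate_identifications(spec)
    write_identifications(rows, outdir / "identifications.tsv")
    write_typing({spec.sample_id: list(spec.alleles)}, outdir / "typing.tsv")
    write_irt_reference(IRT_LANDMARKS, outdir / "irt_reference.tsv")
    targets = [(r.sequence, r.charge) for r in rows if not r.is_decoy]
    spectra, planted = generate_spectra(
        targets,
        seed=spec.seed,
        noise_peaks_mean=spec.spectrum_noise_peaks,
        intensity_sd_log=spec.intensity_sd_log,
        rt_noise_sd_seconds=spec.rt_noise_sd_seconds,
        sample_id=spec.sample_id,
    )
    with open(outdir / "spectra.tsv", "w", newline="\n") as handle:
        handle.write("sequence\tcharge\tprecursor_mz\trt_seconds\tpeaks\n")
        for s in spectra:
            peaks = ";".join(f"{mz:.4f}:{i:.2f}" for mz, i in s.peaks)
            handle.write(
                f"{s.peptide_sequence}\t{s.precursor_charge}"
                f"\t{s.precursor_mz:.4f}\t{s.rt_seconds:.3f}\t{peaks}\n"
            )
    proteins = {
        f"prot_{i:04d}": generate_source_protein(seq, seed=spec.seed + i)
        for i, seq in enumerate(sorted(truth))
    }
    write_fasta(proteins, outdir / "proteins.fasta")
    write_report(
        {
            "generating_allele": truth,
            "planted_irt": {f"{s}/{c}": irt for (s, c), irt in planted.items()},
            "seed": spec.seed,
        },
        outdir / "ground_truth.json",
    )
    return outdir


def read_spectra_tsv(path: str | Path):
    from .library import PeakSpectrum

    spectra = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("sequence\t"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in handle:
            seq, charge, pmz, rt, peaks_field = line.rstrip("\n").split("\t")
            peaks = [
                (float(mz), float(i))
                for mz, i in (p.split(":") for p in peaks_field.split(";") if p)
            ]
            spectra.append(
                PeakSpectrum(
                    peptide_sequence=seq,
                    precursor_charge=int(charge),
                    precursor_mz=float(pmz),
                    peaks=peaks,
                    rt_seconds=float(rt),
                )
            )
    return spectra


def run_pipeline(
    config: RunConfig,
    sample_dir: str | Path,
    outdir: str | Path,
    predictor=None,
) -> dict:
    """Execute all stages on one sample directory; returns the manifest."""
    sample_dir = Path(sample_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if predictor is None:
        predictor = MockPredictor(seed=config.seed)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
        "outputs": {},
    }
    report: dict = {}
    stage = "filter"
    try:
        rows = read_identifications(sample_dir / "identifications.tsv")
        typing = read_typing(sample_dir / "typing.tsv")
        alleles = next(iter(typing.values()))
        peptides = filter_peptides(
            collapse_psms(rows),
            min_probability=config.min_probability,
            min_len=config.min_length,
            max_len=config.max_length,
        )
        manifest["stages"].append(stage)

        stage = "fdr"
        fdr_results = {
            f"{t:g}": fdr_threshold(peptides, t) for t in config.fdr_targets
        }
        report["fdr"] = {
            k: {
                "threshold_probability": r.threshold_probability,
                "n_targets": r.n_targets,
                "n_decoys": r.n_decoys,
                "fdr": r.fdr,
            }
            for k, r in fdr_results.items()
        }
        manifest["stages"].append(stage)

        # downstream stages use the strictest FDR target
        strictest = min(config.fdr_targets)
        passing = apply_threshold(
            peptides, fdr_results[f"{strictest:g}"].threshold_probability
        )

        stage = "annotate"
        records = annotate_peptides(
            [p.sequence for p in passing],
            alleles,
            predictor,
            cutoff=config.cutoff,
            supertype_ic50=config.supertype_ic50,
            include_hla_c=config.include_hla_c,
        )
        by_seq = {r.peptide_sequence: r for r in records}
        report["annotation"] = {
            "status_counts": status_counts(records),
            "per_allele": {
                a: sum(
                    1
                    for r in records
                    if r.status == STATUS_ANNOTATED and r.best_allele == a
                )
                for a in alleles
            },
        }
        with open(outdir / "annotation.tsv", "w", newline="\n") as handle:
            handle.write(
                "sequence\tbest_allele\tscore\tstatus\t"
                + "\t".join(f"ic50_{a}" for a in alleles) + "\n"
            )
            for r in records:
                ic50s = "\t".join(f"{r.ic50_by_allele[a]:.2f}" for a in alleles)
                handle.write(
                    f"{r.peptide_sequence}\t{r.best_allele}\t{r.score:.4f}"
                    f"\t{r.status}\t{ic50s}\n"
                )
        manifest["outputs"]["annotation"] = str(outdir / "annotation.tsv")
        manifest["stages"].append(stage)

        stage = "cfdr"
        cfdr = corrected_fdr(passing, by_seq)
        report["cfdr"] = {
            "n_targets": cfdr.n_targets,
            "n_decoys": cfdr.n_decoys,
            "cfdr": cfdr.fdr,
        }
        manifest["stages"].append(stage)

        stage = "consensus"
        spectra = read_spectra_tsv(sample_dir / "spectra.tsv")
        reference = read_irt_reference(sample_dir / "irt_reference.tsv")
        landmark_seqs = {seq for seq, _ in reference}
        observed = [
            (s.peptide_sequence, s.rt_seconds)
            for s in spectra
            if s.peptide_sequence in landmark_seqs
        ]
        irt_model = fit_irt(observed, reference)
        report["irt"] = {
            "slope": irt_model.slope,
            "intercept": irt_model.intercept,
            "r_squared": irt_model.r_squared,
            "n_landmarks": irt_model.n_landmarks,
        }
        annotated = {
            seq for seq, r in by_seq.items() if r.status == STATUS_ANNOTATED
        }
        groups: dict[tuple[str, int], list] = {}
        for s in spectra:
            if s.peptide_sequence in annotated:
                groups.setdefault(
                    (s.peptide_sequence, s.precursor_charge), []
                ).append(s)
        per_allele: dict[str, list] = {a: [] for a in alleles}
        for (seq, _charge), replicates in sorted(groups.items()):
            allele = by_seq[seq].best_allele
            entry = build_consensus(
                replicates,
                irt_model=irt_model,
                allele=allele,
                match_tolerance_th=config.match_tolerance_th,
            )
            per_allele[allele].append(entry)
        library = merge_libraries(per_allele.values())
        library.sort(key=lambda e: e.key)
        write_spectral_library(library, outdir / "library.sptxt")
        report["library"] = {
            "n_entries": len(library),
            "per_allele": {a: len(v) for a, v in per_allele.items()},
        }
        manifest["outputs"]["library"] = str(outdir / "library.sptxt")
        manifest["stages"].append(stage)

        stage = "windows"
        scheme = make_window_scheme(
            config.window_range[0],
            config.window_range[1],
            config.window_width,
            config.window_overlap,
        )
        write_window_file(scheme, outdir / "swaths.txt")
        report["windows"] = {"n_windows": len(scheme)}
        manifest["outputs"]["windows"] = str(outdir / "swaths.txt")
        manifest["stages"].append(stage)

        stage = "assays"
        assays, rejects = build_assay_library(
            library,
            mz_range=config.mz_range,
            min_transitions=config.min_transitions,
            max_transitions=config.max_transitions,
            match_tolerance_th=config.match_tolerance_th,
            excluded_windows=scheme,
        )
        manifest["stages"].append(stage)

        stage = "decoys"
        decoys = (
            generate_decoy_assays(
                assays,
                method=config.decoy_method,
                similarity_threshold_th=config.similarity_threshold_th,
                identity_threshold=config.identity_threshold,
                mz_range=config.mz_range,
                seed=config.seed,
            )
            if assays
            else []
        )
        write_assay_tsv(assays + decoys, outdir / "assays.tsv")
        with open(outdir / "rejects.txt", "w", newline="\n") as handle:
            handle.write("\n".join(rejects) + ("\n" if rejects else ""))
        report["assays"] = {
            "n_target_transitions": len(assays),
            "n_decoy_transitions": len(decoys),
            "n_peptides": len({a.transition_group_id for a in assays}),
            "n_rejected_peptides": len(rejects),
        }
        manifest["outputs"]["assays"] = str(outdir / "assays.tsv")
        manifest["stages"].append(stage)

        stage = "report"
        write_report(report, outdir / "report.json")
        manifest["outputs"]["report"] = str(outdir / "report.json")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    write_report(manifest, outdir / "manifest.json")
    return manifest
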