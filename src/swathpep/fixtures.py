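"""Synthetic ground-truth fixtures: motif-based binding predictor,
identification tables with decoys, and fragment spectra with retention-time
landmarks. Every generator is seed-deterministic."""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import AffinityVector
from .fdr import ScoredPeptide
from .library import PeakSpectrum, theoretical_fragments
from .masses import RESIDUE_MASS, precursor_mz

AMINO_ACIDS = "".join(sorted(RESIDUE_MASS))

# Retention-time landmark kit: 11 peptides with fixed reference iRT values.
IRT_LANDMARKS: tuple[tuple[str, float], ...] = (
    ("LGGNEQVTR", -24.92),
    ("GAGSSEPVTGLDAK", 0.00),
    ("VEATFGVDESNAK", 12.39),
    ("YILAGVENSK", 19.79),
    ("TPVISGGPYEYR", 28.71),
    ("TPVITGAPYEYR", 33.38),
    ("DGLDAASYYAPVR", 42.26),
    ("ADVTPADFSEWSK", 54.62),
    ("GTFIIDPGGVIR", 70.52),
    ("GTFIIDPAAVIR", 87.23),
    ("LFLQFGAQGSPFLK", 100.00),
)

IC50_MAX = 50000.0
IC50_MIN = 1.0

# Textbook class-I anchor preferences per built-in allele.
_DEFAULT_ANCHORS: dict[str, dict[int, str]] = {
    "A02": {2: "LM", 9: "VL"},
    "A03": {2: "LI", 9: "KR"},
    "B07": {2: "P", 9: "LF"},
}


@dataclass(frozen=True)
class MotifModel:
    """Position-weight motif of one allele mapped to an IC50 scale."""

    allele: str
    anchor_residues: Mapping[int, str]  # 1-based position -> preferred residues
    length: int = 9
    anchor_weight: float = 2.0
    steepness: float = 4.0
    midpoint: float = 2.5

    @property
    def anchor_positions(self) -> frozenset[int]:
        return frozenset(self.anchor_residues)

    def _position_score(self, position: int, residue: str) -> float:
        preferred = self.anchor_residues.get(position)
        if preferred is not None:
            return self.anchor_weight if residue in preferred else 0.0
        # small deterministic per-allele background preference
        h = zlib.crc32(f"{self.allele}:{position}:{residue}".encode())
        return 0.2 * (h % 1000) / 1000.0

    def _score_aligned(self, peptide: str) -> float:
        # map peptide positions onto the 9 model positions: N-terminal half
        # to positions 1..4, C-terminal half to positions 6..9 for short
        # peptides; exact for 9-mers
        n = len(peptide)
        score = 0.0
        for i, residue in enumerate(peptide, start=1):
            if i <= math.ceil(n / 2) and i <= self.length:
                pos = i
            else:
                pos = self.length - (n - i)
            if 1 <= pos <= self.length:
                score += self._position_score(pos, residue)
        return score

    def score(self, peptide: str) -> float:
        """Best motif score over 9-mer cores (longer peptides) or the
        gapped alignment (shorter ones)."""
        n = len(peptide)
        if n <= self.length:
            return self._score_aligned(peptide)
        return max(
            self._score_aligned(peptide[i : i + self.length])
            for i in range(n - self.length + 1)
        )

    def ic50(self, peptide: str) -> float:
        """Logistic map from motif score to IC50 (nM); anchor-matched
        peptides land well below 500 nM, background near IC50_MAX."""
        s = self.score(peptide)
        value = IC50_MAX / (1.0 + math.exp(self.steepness * (s - self.midpoint)))
        return min(max(value, IC50_MIN), IC50_MAX)

    def sample_binder(self, rng: np.random.Generator, length: int = 9) -> str:
        residues = [
            str(rng.choice(list(AMINO_ACIDS))) for _ in range(length)
        ]
        for pos, preferred in self.anchor_residues.items():
            if length > self.length:
                # keep all anchors inside the last 9-mer core so the
                # core-scan scorer sees the full motif
                idx = (length - self.length) + pos - 1
            elif pos <= math.ceil(length / 2):
                idx = pos - 1
            else:
                idx = length - (self.length - pos) - 1
            residues[idx] = preferred[int(rng.integers(len(preferred)))]
        return "".join(residues)


def default_models(alleles: Sequence[str] = ("A02", "A03", "B07")) -> dict[str, MotifModel]:
    models = {}
    for allele in alleles:
        if allele not in _DEFAULT_ANCHORS:
            raise ValueError(
                f"no built-in motif for allele {allele!r}; "
                f"available: {sorted(_DEFAULT_ANCHORS)}"
            )
        models[allele] = MotifModel(allele, _DEFAULT_ANCHORS[allele])
    return models


class MockPredictor:
    """Deterministic motif-based stand-in for an external IC50 predictor.

    Satisfies the predictor contract: callable on (peptides, alleles),
    returning one :class:`AffinityVector` per peptide. Optional log10-normal
    multiplicative noise is reproducible per (seed, peptide, allele), so
    predictions do not depend on batch composition or order.
    """

    def __init__(
        self,
        models: Mapping[str, MotifModel] | None = None,
        noise_sd_log10: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.models = dict(models) if models is not None else default_models()
        self.noise_sd_log10 = noise_sd_log10
        self.seed = seed

    def __call__(
        self, peptides: Sequence[str], alleles: Sequence[str]
    ) -> list[AffinityVector]:
        for allele in alleles:
            if allele not in self.models:
                raise KeyError(f"unknown allele {allele!r}")
        out = []
        for peptide in peptides:
            ic50s = {}
            for allele in alleles:
                value = self.models[allele].ic50(peptide)
                if self.noise_sd_log10 > 0:
                    rng = np.random.default_rng(
                        (self.seed & 0xFFFFFFFF)
                        ^ zlib.crc32(f"{peptide}|{allele}".encode())
                    )
                    value *= 10.0 ** rng.normal(0.0, self.noise_sd_log10)
                    value = min(max(value, IC50_MIN), IC50_MAX)
                ic50s[allele] = value
            out.append(AffinityVector(peptide, ic50s))
        return out


def mock_predict(
    peptides: Sequence[str],
    alleles: Sequence[str],
    model_set: Mapping[str, MotifModel] | None = None,
    noise_sd_log10: float = 0.0,
    seed: int = 0,
) -> list[AffinityVector]:
    """Functional form of :class:`MockPredictor`."""
    return MockPredictor(model_set, noise_sd_log10, seed)(peptides, alleles)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_peptides_per_allele: int = 100
    alleles: tuple[str, ...] = ("A02", "A03", "B07")
    decoy_fraction: float = 0.2
    length_choices: tuple[int, ...] = (8, 9, 9, 9, 10, 11, 12)
    target_prob_range: tuple[float, float] = (0.72, 1.0)
    decoy_prob_range: tuple[float, float] = (0.0, 0.95)
    rt_gradient_minutes: float = 60.0
    prediction_noise_sd_log10: float = 0.0
    spectrum_noise_peaks: float = 0.0  # Poisson mean of extra noise peaks
    intensity_sd_log: float = 0.5
    rt_noise_sd_seconds: float = 0.0
    sample_id: str = "synthetic"


def generate_identifications(
    spec: FixtureSpec,
) -> tuple[list[ScoredPeptide], dict[str, str]]:
    """Motif-sampled target peptides plus shuffled decoys.

    Returns the scored-peptide rows and a ground-truth map
    peptide sequence -> generating allele (targets only).
    """
    rng = np.random.default_rng(spec.seed)
    models = default_models(spec.alleles)
    rows: list[ScoredPeptide] = []
    truth: dict[str, str] = {}
    lo, hi = spec.target_prob_range
    for allele in spec.alleles:
        model = models[allele]
        while sum(1 for a in truth.values() if a == allele) < spec.n_peptides_per_allele:
            length = int(rng.choice(spec.length_choices))
            peptide = model.sample_binder(rng, length)
            if peptide in truth:
                continue
            truth[peptide] = allele
            rows.append(
                ScoredPeptide(
                    sequence=peptide,
                    probability=float(rng.uniform(lo, hi)),
                    is_decoy=False,
                    charge=2,
                    sample_id=spec.sample_id,
                    rt_seconds=float(
                        rng.uniform(0, spec.rt_gradient_minutes * 60)
                    ),
                )
            )
    n_decoys = round(spec.decoy_fraction * len(rows))
    dlo, dhi = spec.decoy_prob_range
    targets = [r.sequence for r in rows]
    seen = set(truth)
    i = 0
    while sum(r.is_decoy for r in rows) < n_decoys:
        source = list(targets[i % len(targets)])
        i += 1
        rng.shuffle(source)
        decoy = "".join(source)
        if decoy in seen:
            continue
        seen.add(decoy)
        rows.append(
            ScoredPeptide(
                sequence=decoy,
                probability=float(rng.uniform(dlo, dhi)),
                is_decoy=True,
                charge=2,
                sample_id=spec.sample_id,
                rt_seconds=float(rng.uniform(0, spec.rt_gradient_minutes * 60)),
            )
        )
    return rows, truth


def generate_spectra(
    peptides: Sequence[tuple[str, int]],
    irt_reference: Sequence[tuple[str, float]] = IRT_LANDMARKS,
    rt_slope: float = 3.0,
    rt_intercept: float = 900.0,
    seed: int = 0,
    noise_peaks_mean: float = 0.0,
    intensity_sd_log: float = 0.5,
    rt_noise_sd_seconds: float = 0.0,
    irt_range: tuple[float, float] = (-20.0, 110.0),
    sample_id: str = "synthetic",
) -> tuple[list[PeakSpectrum], dict[tuple[str, int], float]]:
    """Spectra at theoretical b/y m/z plus the landmark peptides.

    RT is a linear function of a planted per-peptide iRT:
    rt = rt_slope * irt + rt_intercept (+ Gaussian noise). Landmarks use
    their reference iRT; other peptides draw a uniform iRT from
    ``irt_range``. Returns the spectra and the planted iRT per peptide ion.
    """
    rng = np.random.default_rng(seed)
    reference = dict(irt_reference)
    spectra: list[PeakSpectrum] = []
    planted: dict[tuple[str, int], float] = {}

    ions = [(seq, 2) for seq in reference] + list(peptides)
    for seq, charge in ions:
        key = (seq, charge)
        if key in planted:
            continue
        irt = reference.get(seq, float(rng.uniform(*irt_range)))
        planted[key] = irt
        rt = rt_slope * irt + rt_intercept
        if rt_noise_sd_seconds > 0:
            rt += float(rng.normal(0.0, rt_noise_sd_seconds))
        peaks = []
        for _, _, _, mz in theoretical_fragments(seq):
            intensity = float(
                np.exp(rng.normal(math.log(1000.0), intensity_sd_log))
            )
            peaks.append((mz, intensity))
        n_noise = int(rng.poisson(noise_peaks_mean)) if noise_peaks_mean > 0 else 0
        for _ in range(n_noise):
            peaks.append(
                (float(rng.uniform(200.0, 1800.0)),
                 float(np.exp(rng.normal(math.log(200.0), intensity_sd_log))))
            )
        spectra.append(
            PeakSpectrum(
                peptide_sequence=seq,
                precursor_charge=charge,
                precursor_mz=precursor_mz(seq, charge),
                peaks=peaks,
                rt_seconds=rt,
                sample_id=sample_id,
            )
        )
    return spectra, planted


def generate_source_protein(
    peptide: str,
    flank_length: int = 20,
    seed: int = 0,
) -> str:
    """Random protein containing the peptide, for percentile-rank fixtures."""
    rng = np.random.default_rng(seed)
    flank = lambda n: "".join(rng.choice(list(AMINO_ACIDS), size=n))  # noqa: E731
    return flank(flank_length) + peptide + flank(flank_length)
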