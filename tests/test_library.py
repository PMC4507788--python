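"""Consensus spectra, iRT normalization, transition selection, decoys and
library merging."""

import numpy as np
import pytest

from swathpep.fixtures import IRT_LANDMARKS, generate_spectra
from swathpep.library import (
    ConsensusEntry,
    PeakSpectrum,
    build_assay_library,
    build_consensus,
    fit_irt,
    generate_decoy_assays,
    merge_libraries,
    select_transitions,
    theoretical_fragments,
)
from swathpep.masses import fragment_mz, precursor_mz
from swathpep.windows import assign_precursor_window, make_window_scheme


def _spectrum(seq="ALDEKVHTK", charge=2, peaks=None, rt=1000.0):
    if peaks is None:
        peaks = [(mz, 100.0) for _, _, _, mz in theoretical_fragments(seq)]
    return PeakSpectrum(
        peptide_sequence=seq,
        precursor_charge=charge,
        precursor_mz=precursor_mz(seq, charge),
        peaks=peaks,
        rt_seconds=rt,
    )


def _entry(seq="ALDEKVHTK", charge=2, peaks=None, irt=50.0, allele="A02",
           n_replicates=1):
    if peaks is None:
        peaks = sorted(
            (mz, 100.0 + i) for i, (_, _, _, mz) in
            enumerate(theoretical_fragments(seq))
        )
    return ConsensusEntry(
        peptide_sequence=seq,
        precursor_charge=charge,
        precursor_mz=precursor_mz(seq, charge),
        consensus_peaks=peaks,
        irt=irt,
        allele=allele,
        n_replicates=n_replicates,
    )


class TestFitIrt:
    def test_identity_mapping(self):
        observed = [(seq, irt) for seq, irt in IRT_LANDMARKS]
        model = fit_irt(observed, IRT_LANDMARKS)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0)
        assert model.n_landmarks == 11

    def test_noiseless_line_closed_form(self):
        # rt = 2 * irt + 5  =>  irt = 0.5 * rt - 2.5
        observed = [(seq, 2 * irt + 5) for seq, irt in IRT_LANDMARKS]
        model = fit_irt(observed, IRT_LANDMARKS)
        assert model.slope == pytest.approx(0.5)
        assert model.intercept == pytest.approx(-2.5)
        assert model.r_squared == pytest.approx(1.0)

    def test_round_trip_to_1e9(self):
        observed = [(seq, 3.3 * irt + 907.0) for seq, irt in IRT_LANDMARKS]
        model = fit_irt(observed, IRT_LANDMARKS)
        for _, rt in observed:
            assert model.irt_to_rt(model.rt_to_irt(rt)) == pytest.approx(
                rt, abs=1e-9
            )

    def test_noisy_landmarks_recover_slope(self, rng):
        true_slope, true_intercept, sd = 2.0, 300.0, 5.0
        observed = [
            (seq, true_slope * irt + true_intercept + float(rng.normal(0, sd)))
            for seq, irt in IRT_LANDMARKS
        ]
        model = fit_irt(observed, IRT_LANDMARKS)
        # fitting rt -> irt, so truth is 1/true_slope
        x = np.array([rt for _, rt in observed])
        resid_se = sd / true_slope / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(model.slope - 1 / true_slope) < 3 * resid_se

    def test_too_few_landmarks(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_irt([("LGGNEQVTR", 100.0)], IRT_LANDMARKS)

    def test_negative_slope_rejected(self):
        observed = [(seq, -2 * irt + 500) for seq, irt in IRT_LANDMARKS]
        with pytest.raises(ValueError, match="slope"):
            fit_irt(observed, IRT_LANDMARKS)


class TestBuildConsensus:
    def test_single_replicate_is_identity(self):
        spectrum = _spectrum()
        entry = build_consensus([spectrum])
        assert entry.consensus_peaks == spectrum.peaks
        assert entry.irt == spectrum.rt_seconds
        assert entry.n_replicates == 1

    def test_majority_vote_drops_unique_noise_peak(self):
        base = [(200.0, 100.0), (300.0, 110.0), (400.0, 90.0)]
        reps = [
            _spectrum(peaks=list(base)),
            _spectrum(peaks=list(base)),
            _spectrum(peaks=base + [(555.5, 1e6)]),  # noise in one replicate
        ]
        entry = build_consensus(reps)
        assert all(abs(mz - 555.5) > 0.05 for mz, _ in entry.consensus_peaks)
        assert len(entry.consensus_peaks) == 3

    def test_median_intensity(self):
        reps = [
            _spectrum(peaks=[(200.0, 100.0)]),
            _spectrum(peaks=[(200.01, 110.0)]),
            _spectrum(peaks=[(199.99, 500.0)]),
        ]
        entry = build_consensus(reps)
        assert len(entry.consensus_peaks) == 1
        assert entry.consensus_peaks[0][1] == pytest.approx(110.0)

    def test_median_irt(self):
        reps = [_spectrum(rt=100.0), _spectrum(rt=200.0), _spectrum(rt=900.0)]
        assert build_consensus(reps).irt == 200.0

    def test_mixed_ions_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            build_consensus([_spectrum("ALDEKVHTK"), _spectrum("KLEEQARAK")])

    def test_two_replicates_keep_all_peaks(self):
        reps = [
            _spectrum(peaks=[(200.0, 100.0)]),
            _spectrum(peaks=[(200.0, 100.0), (300.0, 50.0)]),
        ]
        assert len(build_consensus(reps).consensus_peaks) == 2


class TestSelectTransitions:
    def test_six_most_intense_by_exhaustive_ranking(self, rng):
        seq = "ALDEKVHTKWR"
        frags = [
            (t, o, c, mz)
            for t, o, c, mz in theoretical_fragments(seq)
            if 350 <= mz <= 2000
        ]
        rng.shuffle(frags)
        frags = frags[:12]
        intensities = rng.uniform(10, 1000, size=len(frags))
        peaks = sorted(
            (mz, float(i)) for (_, _, _, mz), i in zip(frags, intensities)
        )
        entry = _entry(seq, peaks=peaks)
        selected = select_transitions(entry)
        assert len(selected) == 6
        expected = set(
            round(mz, 4)
            for (_, _, _, mz), _ in sorted(
                zip(frags, intensities), key=lambda p: -p[1]
            )[:6]
        )
        assert {round(t.fragment_mz, 4) for t in selected} == expected
        # library intensities must be the matched peak intensities
        by_mz = {round(mz, 4): i for mz, i in peaks}
        for t in selected:
            assert t.library_intensity == pytest.approx(by_mz[round(t.fragment_mz, 4)])

    def test_fewer_than_min_transitions_drops_peptide(self):
        seq = "ALDEKVHTK"
        frags = [
            mz for _, _, _, mz in theoretical_fragments(seq) if 350 <= mz <= 2000
        ][:5]
        entry = _entry(seq, peaks=[(mz, 100.0) for mz in sorted(frags)])
        assert select_transitions(entry) == []

    def test_rejects_logged_by_library_builder(self):
        good = _entry("ALDEKVHTK")
        bad = _entry("KLEEQARAK", peaks=[(400.0, 100.0)])  # unannotatable peak
        assays, rejects = build_assay_library([good, bad])
        assert rejects == ["KLEEQARAK/2"]
        assert {a.transition_group_id for a in assays} == {"ALDEKVHTK/2"}

    def test_fragment_outside_mz_range_excluded(self):
        entry = _entry("ALDEKVHTK")
        entry.consensus_peaks = entry.consensus_peaks + [(2100.0, 1e9)]
        selected = select_transitions(entry)
        assert all(350 <= t.fragment_mz <= 2000 for t in selected)

    def test_precursor_own_window_exclusion(self):
        scheme = make_window_scheme(400, 1200, 25)
        entry = _entry("ALDEKVHTK")
        own = assign_precursor_window(entry.precursor_mz, scheme)
        core = scheme.core(own)
        selected = select_transitions(entry, excluded_windows=scheme)
        assert selected, "expected enough fragments outside the own window"
        for t in selected:
            assert not (core[0] <= t.fragment_mz < core[1])

    def test_transition_constraints_property(self, rng):
        # acceptance-style sweep: constraints hold on 1000 random peptides
        from conftest import random_peptide

        n_retained = 0
        for _ in range(1000):
            seq = random_peptide(rng)
            entry = _entry(seq, peaks=sorted(
                (mz, float(rng.uniform(10, 1000)))
                for _, _, _, mz in theoretical_fragments(seq)
            ))
            selected = select_transitions(entry)
            qualifying = {
                mz
                for _, _, _, mz in theoretical_fragments(seq)
                if 350 <= mz <= 2000
            }
            if len(qualifying) < 6:
                assert selected == []
                continue
            n_retained += 1
            assert len(selected) == 6
            for t in selected:
                assert t.fragment_type in ("b", "y")
                assert t.fragment_charge in (1, 2)
                assert 350 <= t.fragment_mz <= 2000
        assert n_retained > 0


class TestDecoyAssays:
    def _assays(self, seqs, seed=0):
        entries = [_entry(seq) for seq in seqs]
        assays, _ = build_assay_library(entries)
        return assays

    def test_homopolymer_yields_no_decoy(self):
        assays = self._assays(["AAAAAAAAAAK", "ALDEKVHTK"])
        # make one group a homopolymer by hand
        from dataclasses import replace

        homopolymer = [
            replace(a, peptide_sequence="AAAAAAAAA",
                    transition_group_id="AAAAAAAAA/2")
            for a in assays
            if a.peptide_sequence == "AAAAAAAAAAK"
        ]
        decoys = generate_decoy_assays(homopolymer, seed=1)
        assert decoys == []

    def test_no_decoy_identical_to_any_target(self, rng):
        from conftest import random_peptide

        seqs = {random_peptide(rng, length=10) for _ in range(50)}
        assays = self._assays(sorted(seqs))
        decoys = generate_decoy_assays(assays, seed=3)
        target_seqs = {a.peptide_sequence for a in assays}
        assert decoys
        for d in decoys:
            assert d.is_decoy
            assert d.peptide_sequence not in target_seqs
            assert d.transition_group_id.startswith("DECOY_")

    def test_c_terminus_fixed_and_composition_preserved(self):
        assays = self._assays(["ALDEKVHTR"])
        decoys = generate_decoy_assays(assays, seed=5)
        assert decoys
        decoy_seq = decoys[0].peptide_sequence
        assert decoy_seq[-1] == "R"
        assert sorted(decoy_seq) == sorted("ALDEKVHTR")

    def test_seed_determinism_and_mass_oracle(self, rng):
        from conftest import random_peptide
        from test_masses import oracle_fragment_mz

        seqs = sorted({random_peptide(rng) for _ in range(100)})
        assays = self._assays(seqs)
        decoys_a = generate_decoy_assays(assays, seed=42)
        decoys_b = generate_decoy_assays(list(reversed(assays)), seed=42)
        assert sorted(map(repr, decoys_a)) == sorted(map(repr, decoys_b))
        for d in decoys_a:
            assert d.fragment_mz == pytest.approx(
                oracle_fragment_mz(
                    d.peptide_sequence, d.fragment_type, d.fragment_ordinal,
                    d.fragment_charge,
                ),
                abs=1e-4,
            )

    def test_reverse_method(self):
        assays = self._assays(["ALDEKVHTR"])
        decoys = generate_decoy_assays(assays, method="reverse", seed=0)
        assert decoys[0].peptide_sequence == "THVKEDLAR"


class TestMergeLibraries:
    def test_disjoint_union(self):
        a02 = [_entry("ALDEKVHTK", allele="A02")]
        b07 = [_entry("KLEEQARAK", allele="B07")]
        merged = merge_libraries([a02, b07])
        assert len(merged) == 2
        assert {e.allele for e in merged} == {"A02", "B07"}

    def test_collision_keeps_more_replicates(self):
        older = _entry("ALDEKVHTK", n_replicates=2)
        newer = _entry("ALDEKVHTK", n_replicates=5, allele="B07")
        merged = merge_libraries([[older], [newer]])
        assert len(merged) == 1
        assert merged[0].n_replicates == 5
        assert merged[0].allele == "B07"

    def test_collision_tie_breaks_on_intensity(self):
        low = _entry("ALDEKVHTK", peaks=[(400.0, 10.0)] * 1)
        high = _entry("ALDEKVHTK", peaks=[(400.0, 999.0)])
        merged = merge_libraries([[low], [high]])
        assert merged[0].total_intensity == 999.0

    def test_count_matches_inclusion_exclusion(self, rng):
        from conftest import random_peptide

        pool = sorted({random_peptide(rng, length=9) for _ in range(60)})
        lib_a = [_entry(s) for s in pool[:40]]
        lib_b = [_entry(s) for s in pool[20:]]
        merged = merge_libraries([lib_a, lib_b])
        expected = len({e.key for e in lib_a} | {e.key for e in lib_b})
        assert len(merged) == expected


class TestZeroNoiseFixturePipeline:
    def test_all_generated_peptides_yield_full_assays(self, rng):
        from conftest import random_peptide

        peptides = sorted({(random_peptide(rng, length=9), 2) for _ in range(40)})
        spectra, planted = generate_spectra(peptides, seed=0, noise_peaks_mean=0.0)
        observed = [
            (s.peptide_sequence, s.rt_seconds)
            for s in spectra
            if any(s.peptide_sequence == seq for seq, _ in IRT_LANDMARKS)
        ]
        model = fit_irt(observed, IRT_LANDMARKS)
        # planted line: rt = 3 * irt + 900 -> exact recovery at zero noise
        assert model.slope == pytest.approx(1 / 3)
        assert model.intercept == pytest.approx(-300.0)
        entries = [
            build_consensus([s], irt_model=model)
            for s in spectra
            if (s.peptide_sequence, 2) in peptides
        ]
        assays, rejects = build_assay_library(entries)
        assert rejects == []
        groups = {a.transition_group_id for a in assays}
        assert len(groups) == len(peptides)
        assert len(assays) == 6 * len(peptides)
        # planted iRT reproduced through the fitted model
        for entry in entries:
            assert entry.irt == pytest.approx(
                planted[(entry.peptide_sequence, 2)], abs=1e-6
            )
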