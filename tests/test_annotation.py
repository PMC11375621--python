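"""Spectral cosine, Tanimoto, and consensus-annotation rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntsprio.annotation import (
    AnnotationCandidate,
    ConsensusConfig,
    LibrarySpectrum,
    consensus_annotate,
    cosine_score,
    library_match,
    tanimoto,
)
from ntsprio.features import MS2Spectrum


def spec(peaks, precursor=300.0):
    return MS2Spectrum(precursor, 500.0, None, peaks)


class TestCosine:
    def test_identical_spectra_score_one(self):
        s = spec([(100.0, 100.0), (150.0, 40.0), (200.0, 10.0)])
        assert cosine_score(s, s) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        a = spec([(100.0, 100.0)])
        b = spec([(200.0, 100.0)])
        assert cosine_score(a, b) == 0.0

    def test_partial_overlap_hand_value(self):
        # one matched pair: 100*50 / sqrt((100^2+50^2)(50^2+100^2)) = 0.4
        a = spec([(100.0, 100.0), (200.0, 50.0)])
        b = spec([(100.0, 50.0), (300.0, 100.0)])
        assert cosine_score(a, b) == pytest.approx(0.4, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = spec([(float(m), float(i)) for m, i in zip(rng.uniform(50, 290, 8), rng.uniform(1, 100, 8))])
        b = spec([(float(m), float(i)) for m, i in zip(rng.uniform(50, 290, 8), rng.uniform(1, 100, 8))])
        assert cosine_score(a, b) == pytest.approx(cosine_score(b, a), abs=1e-12)

    def test_empty_spectrum_errors(self):
        with pytest.raises(ValueError):
            cosine_score(spec([(100.0, 1.0)]), spec([]))

    def test_matches_optimal_assignment_oracle(self):
        """Exhaustive-assignment oracle on small spectra whose peaks are
        spaced so each peak has at most one in-tolerance partner."""
        rng = np.random.default_rng(9)
        for _ in range(30):
            grid = np.arange(100.0, 100.0 + 0.05 * 12, 0.05)
            mz_a = rng.choice(grid, size=5, replace=False) + rng.uniform(-0.002, 0.002, 5)
            mz_b = rng.choice(grid, size=5, replace=False) + rng.uniform(-0.002, 0.002, 5)
            int_a = rng.uniform(1, 100, 5)
            int_b = rng.uniform(1, 100, 5)
            a = spec(sorted(zip(mz_a.tolist(), int_a.tolist())))
            b = spec(sorted(zip(mz_b.tolist(), int_b.tolist())))
            best = 0.0
            for perm in itertools.permutations(range(5)):
                dot = sum(
                    a.peaks[i][1] * b.peaks[j][1]
                    for i, j in enumerate(perm)
                    if abs(a.peaks[i][0] - b.peaks[j][0]) <= 0.005
                )
                best = max(best, dot)
            norm = np.sqrt(sum(i**2 for _, i in a.peaks) * sum(i**2 for _, i in b.peaks))
            assert cosine_score(a, b) == pytest.approx(best / norm, abs=1e-12)

    def test_agrees_with_matchms_cosine_greedy(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(17)
        for _ in range(10):
            mz_a = np.sort(rng.choice(np.arange(60.0, 290.0, 0.4), 10, replace=False))
            mz_b = np.where(rng.random(10) < 0.5, mz_a, mz_a + 0.1)
            int_a = rng.uniform(1, 100, 10)
            int_b = rng.uniform(1, 100, 10)
            ours = cosine_score(
                spec(list(zip(mz_a.tolist(), int_a.tolist()))),
                spec(list(zip(mz_b.tolist(), int_b.tolist()))),
            )
            sa = matchms.Spectrum(mz=mz_a, intensities=int_a, metadata_harmonization=False)
            sb = matchms.Spectrum(
                mz=np.sort(mz_b).astype(float),
                intensities=int_b[np.argsort(mz_b)],
                metadata_harmonization=False,
            )
            theirs = float(CosineGreedy(tolerance=0.005).pair(sa, sb)["score"])
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestLibraryMatch:
    def test_self_match_ranks_first(self):
        s = spec([(100.0, 100.0), (150.0, 60.0), (200.0, 30.0)])
        library = [
            LibrarySpectrum("true", s),
            LibrarySpectrum("decoy", spec([(80.0, 100.0), (210.0, 60.0)])),
        ]
        ranked = library_match(s, library)
        assert ranked and ranked[0].structure_id == "true"
        assert ranked[0].score == pytest.approx(1.0)

    def test_nothing_above_threshold(self):
        s = spec([(100.0, 100.0)])
        library = [LibrarySpectrum("decoy", spec([(200.0, 100.0)]))]
        assert library_match(s, library) == []

    def test_threshold_is_strict(self):
        # construct cosine exactly 0.5: matched pair 100*100, norms 100^2 * (100^2+100^2+100^2+100^2)
        q = spec([(100.0, 100.0)])
        entry = spec([(100.0, 100.0), (150.0, 100.0), (200.0, 100.0), (250.0, 100.0)])
        assert cosine_score(q, entry) == pytest.approx(0.5, abs=1e-12)
        assert library_match(q, [LibrarySpectrum("edge", entry)]) == []


class TestTanimoto:
    def test_identical_vectors(self):
        fp = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_vectors(self):
        assert tanimoto("1100", "0011") == 0.0

    def test_one_shared_of_three(self):
        assert tanimoto("1100", "1010") == pytest.approx(1.0 / 3.0)

    def test_all_zero_defined_as_one(self):
        assert tanimoto("0000", "0000") == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            tanimoto("110", "1100")

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.booleans(), min_size=1, max_size=64), st.data())
    def test_matches_set_algebra(self, bits_a, data):
        bits_b = data.draw(
            st.lists(st.booleans(), min_size=len(bits_a), max_size=len(bits_a))
        )
        set_a = {i for i, b in enumerate(bits_a) if b}
        set_b = {i for i, b in enumerate(bits_b) if b}
        union = set_a | set_b
        expected = 1.0 if not union else len(set_a & set_b) / len(union)
        assert tanimoto(np.array(bits_a), np.array(bits_b)) == pytest.approx(expected)


FP = np.ones(16, dtype=bool)


class TestConsensus:
    def test_library_match_gives_level_2b(self):
        cands = [AnnotationCandidate("lib_hit", "library", 0.89, matched_peaks=5)]
        out = consensus_annotate("f1", cands)
        assert (out.structure_id, out.confidence) == ("lib_hit", "2b")

    def test_in_silico_agreement_gives_level_3(self):
        fp_b = FP.copy()
        fp_b[0] = False  # tanimoto 15/16 > 0.8
        cands = [
            AnnotationCandidate("struct", "silico_forward", 0.9, 4, FP),
            AnnotationCandidate("struct", "silico_inverse", 0.8, 4, fp_b),
        ]
        out = consensus_annotate("f1", cands)
        assert (out.structure_id, out.confidence) == ("struct", "3")

    def test_disagreeing_engines_fall_to_formula(self):
        cands = [
            AnnotationCandidate("a", "silico_forward", 0.9, 4, FP),
            AnnotationCandidate("b", "silico_inverse", 0.8, 4, ~FP),
            AnnotationCandidate("C6H6", "formula_only", 1.0),
        ]
        out = consensus_annotate("f1", cands)
        assert (out.structure_id, out.confidence) == ("C6H6", "4")

    def test_too_few_matched_peaks_blocks_level_3(self):
        cands = [
            AnnotationCandidate("a", "silico_forward", 0.9, 2, FP),
            AnnotationCandidate("a", "silico_inverse", 0.8, 4, FP),
        ]
        assert consensus_annotate("f1", cands).confidence == "5"

    def test_formula_only_gives_level_4(self):
        out = consensus_annotate("f1", [AnnotationCandidate("C6H6", "formula_only", 1.0)])
        assert (out.structure_id, out.confidence) == ("C6H6", "4")

    def test_ambiguous_formulas_give_level_5(self):
        cands = [
            AnnotationCandidate("C6H6", "formula_only", 1.0),
            AnnotationCandidate("C7H8", "formula_only", 1.0),
        ]
        assert consensus_annotate("f1", cands).confidence == "5"

    def test_no_candidates_gives_level_5(self):
        out = consensus_annotate("f1", [])
        assert out.structure_id is None and out.confidence == "5"

    def test_level_never_one(self):
        # even a perfect library match stays at 2b (no local standards)
        cands = [AnnotationCandidate("x", "library", 1.0, matched_peaks=10)]
        assert consensus_annotate("f1", cands).confidence == "2b"

    def test_adding_library_candidate_never_lowers_confidence(self):
        base = [
            AnnotationCandidate("s", "silico_forward", 0.9, 4, FP),
            AnnotationCandidate("s", "silico_inverse", 0.8, 4, FP),
        ]
        order = {"2b": 0, "3": 1, "4": 2, "5": 3}
        without = consensus_annotate("f1", base).confidence
        with_lib = consensus_annotate(
            "f1", base + [AnnotationCandidate("lib", "library", 0.9, 5)]
        ).confidence
        assert order[with_lib] <= order[without]

    def test_evidence_records_fired_clause(self):
        out = consensus_annotate(
            "f1", [AnnotationCandidate("lib", "library", 0.9, 5)]
        )
        assert any("Level 2b" in e for e in out.evidence)


def test_clause_attribution_on_synthetic_truth(noise_free_bundle, cascade_result):
    """Every constructed annotation route must resolve to its intended
    confidence level."""
    import warnings

    from ntsprio.annotation import library_match as lm

    b = noise_free_bundle
    truth = b.truth.set_index("feature_id")
    checked = 0
    for f in cascade_result.features:
        expected = truth.loc[f.id, "expected_level"]
        if not isinstance(expected, str):
            continue
        cands = list(b.candidates.get(f.id, []))
        spectrum = cascade_result.spectra.get(f.id)
        if spectrum is not None and b.library:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cands.extend(lm(spectrum, b.library))
        out = consensus_annotate(f.id, cands)
        assert out.confidence == expected, f"{f.id}: {out.evidence}"
        checked += 1
    assert checked >= 50
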