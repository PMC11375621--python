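"""Filter cascade: stage predicates, MS2 assembly, oracle equivalence."""

import warnings

import numpy as np
import pytest

from ntsprio.features import (
    ExperimentDesign,
    Feature,
    MS2Spectrum,
    assemble_ms2,
    classify_peak_quality,
    componentize,
    filter_blank_ratio,
    filter_intensity,
    filter_replicate_rsd,
    run_cascade,
)


def feat(fid, intensities, mz=300.0, rt=500.0, polarity="positive"):
    return Feature(id=fid, mz=mz, rt=rt, polarity=polarity, intensities=intensities)


class TestIntensityFilter:
    @pytest.mark.parametrize(
        "polarity,value,kept",
        [
            ("positive", 100_000, True),  # boundary is inclusive
            ("positive", 99_999, False),
            ("negative", 60_000, True),
            ("negative", 49_999, False),
        ],
    )
    def test_threshold_boundary(self, polarity, value, kept):
        f = feat("f1", {"S1_r1": value}, polarity=polarity)
        assert (f in filter_intensity([f])) is kept

    def test_unknown_polarity_errors(self):
        f = feat("f1", {"S1_r1": 1e6})
        with pytest.raises(ValueError):
            filter_intensity([f], {"negative": 1.0})


class TestRsdFilter:
    @pytest.mark.parametrize(
        "values,kept",
        [
            ((100_000, 150_000, 200_000), True),  # RSD 33.3%
            ((100_000, 300_000, 800_000), False),  # RSD 90.1%
            ((250_000, 250_000, 250_000), True),  # RSD 0
        ],
    )
    def test_rsd_examples(self, triplicate_design, values, kept):
        f = feat("f1", dict(zip(["S1_r1", "S1_r2", "S1_r3"], values)))
        assert (f in filter_replicate_rsd([f], triplicate_design)) is kept

    def test_requires_presence_in_all_replicates_of_a_sample(self, triplicate_design):
        f = feat("f1", {"S1_r1": 1e6, "S1_r2": 1e6})  # r3 missing
        assert filter_replicate_rsd([f], triplicate_design) == []

    def test_any_sample_suffices(self, triplicate_design):
        intens = {"S1_r1": 1e5, "S1_r2": 9e5, "S1_r3": 3e6}  # bad RSD in S1
        intens.update({"S2_r1": 1e6, "S2_r2": 1.1e6, "S2_r3": 0.9e6})  # good in S2
        f = feat("f1", intens)
        assert filter_replicate_rsd([f], triplicate_design) == [f]

    def test_single_replicate_errors(self):
        design = ExperimentDesign(samples={"S1": ["S1_r1"]})
        with pytest.raises(ValueError):
            filter_replicate_rsd([feat("f1", {"S1_r1": 1e6})], design)


class TestBlankFilter:
    def test_strictly_exceeds_factor(self, triplicate_design):
        reps = {"S1_r1": 301_000, "S1_r2": 301_000, "S1_r3": 301_000}
        blanks = {"B1": 100_000, "B2": 100_000}
        assert filter_blank_ratio([feat("f1", {**reps, **blanks})], triplicate_design)

    def test_exactly_factor_is_removed(self, triplicate_design):
        reps = {"S1_r1": 300_000, "S1_r2": 300_000, "S1_r3": 300_000}
        blanks = {"B1": 100_000, "B2": 100_000}
        assert filter_blank_ratio([feat("f1", {**reps, **blanks})], triplicate_design) == []

    def test_zero_blank_passes_any_signal(self, triplicate_design):
        f = feat("f1", {"S1_r1": 1.0})
        assert filter_blank_ratio([f], triplicate_design) == [f]

    def test_no_blanks_warns_and_passes(self):
        design = ExperimentDesign(samples={"S1": ["S1_r1", "S1_r2"]})
        f = feat("f1", {"S1_r1": 1.0, "S1_r2": 1.0})
        with pytest.warns(UserWarning):
            assert filter_blank_ratio([f], design) == [f]


class TestPeakQuality:
    def test_gaussian_is_high(self):
        x = np.linspace(-2.5, 2.5, 20)
        assert classify_peak_quality(feat("f1", {}), np.exp(-0.5 * x**2)) == "high"

    def test_two_point_spike_is_low(self):
        assert classify_peak_quality(feat("f1", {}), np.array([0.0, 1e5])) == "low"

    def test_constant_zero_is_low(self):
        assert classify_peak_quality(feat("f1", {}), np.zeros(20)) == "low"

    def test_bimodal_is_low(self):
        x = np.linspace(-3, 3, 40)
        trace = np.exp(-0.5 * (x - 1.5) ** 2) + np.exp(-0.5 * (x + 1.5) ** 2)
        assert classify_peak_quality(feat("f1", {}), trace) == "low"

    def test_missing_eic_passes_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_peak_quality(feat("f1", {}), None) == "high"

    def test_custom_classifier_exceptions_carry_feature_id(self):
        def boom(feature, eic):
            raise RuntimeError("nope")

        with pytest.raises(RuntimeError, match="f1"):
            classify_peak_quality(feat("f1", {}), None, classifier=boom)


class TestComponentize:
    def test_sodiated_partner_dropped(self):
        a = feat("a", {}, mz=300.0, rt=500.0)
        b = feat("b", {}, mz=300.0 + 21.98194, rt=501.0)
        kept, dropped = componentize([a, b])
        assert kept == [a] and dropped == {"b": "Na-H"}

    def test_carbon13_partner_dropped(self):
        a = feat("a", {}, mz=300.0, rt=500.0)
        b = feat("b", {}, mz=301.00336, rt=500.5)
        kept, dropped = componentize([a, b])
        assert kept == [a] and "b" in dropped

    def test_isolated_feature_kept(self):
        a = feat("a", {}, mz=300.0)
        kept, dropped = componentize([a])
        assert kept == [a] and not dropped

    def test_non_coeluting_pair_kept(self):
        a = feat("a", {}, mz=300.0, rt=500.0)
        b = feat("b", {}, mz=321.981944, rt=520.0)
        kept, _ = componentize([a, b])
        assert len(kept) == 2


class TestAssembleMs2:
    def test_sub5pct_fragment_pruned(self):
        f = feat("f1", {}, mz=300.0, rt=500.0)
        s = MS2Spectrum(300.0, 500.0, 30.0, [(100.0, 1000.0), (150.0, 500.0), (200.0, 40.0)])
        merged = assemble_ms2(f, [s])
        assert merged is not None and len(merged.peaks) == 2

    def test_precursor_outside_half_window_excluded(self):
        f = feat("f1", {}, mz=300.0, rt=500.0)
        s = MS2Spectrum(300.21, 500.0, 30.0, [(100.0, 1000.0)])
        assert assemble_ms2(f, [s]) is None

    def test_cross_energy_average_prunes_weak_fragment(self):
        f = feat("f1", {}, mz=300.0, rt=500.0)
        s1 = MS2Spectrum(300.0, 500.0, 30.0, [(100.0, 1000.0), (150.0, 80.0)])
        s2 = MS2Spectrum(300.0, 500.0, 70.0, [(100.0, 1000.0), (150.0, 10.0)])
        merged = assemble_ms2(f, [s1, s2])
        # fragment 150: (8 + 1)/2 = 4.5 < 5 -> pruned; base peak survives
        assert [round(m) for m, _ in merged.peaks] == [100]

    def test_rt_outside_half_window_excluded(self):
        f = feat("f1", {}, mz=300.0, rt=500.0)
        s = MS2Spectrum(300.0, 503.0, 30.0, [(100.0, 1000.0)])
        assert assemble_ms2(f, [s]) is None


# --- independent brute-force oracle --------------------------------------

def oracle_survivors(features, design, thresholds, max_rsd, factor):
    """From-definition reimplementation of the three numeric predicates."""
    out = []
    for f in features:
        if max(f.intensities.values(), default=0.0) < thresholds[f.polarity]:
            continue
        ok_rsd = False
        for reps in design.samples.values():
            vals = [f.intensities.get(r) for r in reps]
            if all(v is not None and v > 0 for v in vals):
                mean = sum(vals) / len(vals)
                sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
                if 100.0 * sd / mean <= max_rsd:
                    ok_rsd = True
                    break
        if not ok_rsd:
            continue
        blank_mean = sum(f.intensities.get(b, 0.0) for b in design.blanks) / len(design.blanks)
        best = max(
            sum(f.intensities.get(r, 0.0) for r in reps) / len(reps)
            for reps in design.samples.values()
        )
        if best > factor * blank_mean:
            out.append(f.id)
    return set(out)


def random_features(rng, n, design):
    feats = []
    reps = design.replicate_ids
    for i in range(n):
        polarity = "positive" if rng.random() < 0.5 else "negative"
        intens = {}
        for r in reps:
            if rng.random() < 0.8:
                intens[r] = float(10 ** rng.uniform(3.5, 6.5))
        if not intens:
            intens[reps[0]] = 1000.0
        feats.append(
            Feature(
                id=f"r{i}", mz=float(rng.uniform(100, 1000)),
                rt=float(rng.uniform(0, 1500)), polarity=polarity, intensities=intens,
            )
        )
    return feats


def test_cascade_matches_brute_force_oracle(triplicate_design):
    rng = np.random.default_rng(42)
    feats = random_features(rng, 200, triplicate_design)
    thresholds = {"positive": 100_000.0, "negative": 50_000.0}
    expected = oracle_survivors(feats, triplicate_design, thresholds, 50.0, 3.0)
    stage1 = filter_intensity(feats, thresholds)
    stage2 = filter_replicate_rsd(stage1, triplicate_design, 50.0)
    stage3 = filter_blank_ratio(stage2, triplicate_design, 3.0)
    assert {f.id for f in stage3} == expected


def test_stage_monotonicity_and_order(triplicate_design):
    rng = np.random.default_rng(3)
    feats = random_features(rng, 120, triplicate_design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_cascade(feats, triplicate_design)
    assert result.trace.stage_names() == [
        "intensity", "replicate_rsd", "blank_ratio",
        "peak_quality", "componentization", "ms2_assembly",
    ]
    counts = [(n_in, n_out) for _, n_in, n_out in result.trace.stages]
    assert all(n_out <= n_in for n_in, n_out in counts)
    # consecutive stages chain: output of one is input of the next
    for (_, prev_out), (next_in, _) in zip(counts, counts[1:]):
        assert next_in == prev_out


def test_cascade_deterministic(triplicate_design):
    rng = np.random.default_rng(5)
    feats = random_features(rng, 80, triplicate_design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = run_cascade(feats, triplicate_design)
        r2 = run_cascade(feats, triplicate_design)
    assert [f.id for f in r1.features] == [f.id for f in r2.features]
    assert r1.trace.stages == r2.trace.stages


def test_empty_input_gives_zero_trace(triplicate_design):
    result = run_cascade([], triplicate_design)
    assert result.features == []
    assert all(n_in == 0 and n_out == 0 for _, n_in, n_out in result.trace.stages)
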