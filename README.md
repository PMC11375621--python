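# ntsprio

Risk-based suspect and non-targeted screening for LC-ESI-HRMS feature
data: quality filtering, suspect-list matching, consensus structural
annotation, semi-quantification, and toxicity-weighted priority ranking.

Non-targeted screening of a complex extract (textiles, water, biota)
yields tens of thousands of aligned LC-HRMS features per run, almost all
of which are noise, blank carry-over, redundant adduct/isotope peaks, or
chemicals of no concern. `ntsprio` implements the full funnel that turns
such a table into a short ranked list of chemicals worth follow-up with
reference standards. It is aimed at environmental and analytical chemists
who already have aligned feature tables (e.g. from XCMS), DDA MS² peak
lists, suspect lists (NORMAN SLE style), and candidate tables from
external annotation engines — and want a tested, reproducible pipeline
over them.

## What it computes

**Filter cascade.** Features pass, in order: a polarity-specific intensity
threshold (defaults 100,000 positive / 50,000 negative counts), a
replicate-reproducibility filter (detected in every replicate of at least
one sample with RSD ≤ 50%), a blank filter (best per-sample mean > 3× the
mean method-blank intensity), an EIC peak-quality check (pluggable
classifier; transparent heuristic default), componentization (co-eluting
adduct/isotope partners collapse onto the protonated/deprotonated
species), and MS² assembly (per-feature merge of DDA spectra across
collision energies inside a 0.4 Da precursor / 5 s RT window, pruning
fragments below 5% average relative intensity).

**Suspect screening.** Candidate ions ([M+H]⁺; [M−H]⁻ and [M+Cl]⁻) are
computed from each suspect's formula or exact mass and matched to feature
m/z within ±2 mDa. A linear retention-time-index model, RTI = a·RT + b
fitted on calibrants, predicts each suspect's RT; matches deviating more
than ±120 s are flagged as implausible.

**Consensus annotation.** Library matches use greedy matched-peak cosine
similarity (unmatched peaks penalize the norms); in-silico engines agree
when their top candidates' fingerprints have Tanimoto > 0.8 and each
matches > 2 MS² peaks. Confidence follows the Schymanski scale: Level 2b
(library match), 3 (concordant in-silico structure), 4 (unequivocal
formula), 5 (unknown). Level 1 requires local reference standards and is
never emitted.

**Quantification and priority.** Response factors (area per µM, fit
through the origin) from calibration chemicals detected at ≥ 5 levels
anchor a transfer model log₁₀(RF) = s·logIE + c, which converts any
feature's predicted ionization efficiency and integrated area into a
concentration. The priority score is the predicted hazard quotient

    priority = predicted concentration (mM) / predicted LC₅₀ (mM)

used strictly to rank features against one another, never as an absolute
risk value.

**Validation.** Against spiked ground truth, TPR = TP/(TP+FN),
precision = TP/(TP+FP), F1 = harmonic mean — where a wrongly annotated
feature counts toward *both* FN and FP (see `docs/methods.md`).

A seeded synthetic-data generator (`ntsprio.synthetic`) produces complete
truth-labeled experiments — feature tables, EICs, MS² spectra, a spectral
library, suspect lists, calibration curves and candidate tables — so the
entire pipeline is testable without instrument data.

## Worked example

```sh
ntsprio simulate --seed 42 --out demo/bundle
# wrote bundle with 108 features, 114 spectra, 53 suspects -> demo/bundle

ntsprio filter --features demo/bundle/features.csv \
    --design demo/bundle/design.csv --spectra demo/bundle/spectra.mgf \
    --eics demo/bundle/eics.csv --out demo/out
# intensity              108 ->     102 (94.4%)
# replicate_rsd          102 ->      96 (88.9%)
# blank_ratio             96 ->      90 (83.3%)
# peak_quality            90 ->      84 (77.8%)
# componentization        84 ->      78 (72.2%)
# ms2_assembly            78 ->      78 (72.2%)

ntsprio suspects --features demo/out/filtered_features.csv \
    --design demo/bundle/design.csv --list SYN demo/bundle/suspects.csv \
    --calibrants demo/bundle/rti_calibrants.csv --out demo/out/matches.csv
# SYN: 38 features matched (0 multi-matched), 38 pass RT filter

ntsprio annotate --spectra demo/out/assembled_ms2.mgf \
    --library demo/bundle/library.msp \
    --candidates demo/bundle/candidates.csv --out demo/out/annotations.csv
# annotations by level: 2b: 13, 3: 13, 4: 12
```

The funnel lines read "stage, features in → features out (percent of the
original input surviving)". Of 108 simulated features, the 30 constructed
to fail a specific filter are removed at exactly that stage; all 38
spiked chemicals are recovered by the suspect screen and pass the RT
plausibility filter, and each annotated feature resolves to the
confidence level its candidate evidence supports. `ntsprio prioritize`
and `ntsprio validate` continue the chain (see `--help`).

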