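# Methods

This note documents the models and numerical conventions behind
`ntsprio`, the design choices made where the underlying procedure was
genuinely open, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## Mass arithmetic

Neutral monoisotopic masses are sums of principal-isotope masses over a
pinned table (¹²C = 12 exactly; H 1.00782503207, O 15.9949146196,
N 14.0030740048, P 30.97376163, S 31.97207100, F 18.99840322,
Cl 34.96885268, Br 78.9183371, Si 27.9769265325 Da). The supported
element set is the alphabet commonly used for small-molecule formula
generation (C, H, O, N, P, S, F, Cl, Br) plus Si, which siloxane
surfactants require. Constants live in source, not behind a runtime
dependency, so results are bit-stable across platforms.

Ion masses use the proton convention: [M+H]⁺ adds 1.007276 Da (an H atom
minus an electron), [M−H]⁻ subtracts it, and [M+Cl]⁻ adds 34.969402 Da
(a Cl atom plus an electron). Only these three singly charged adducts
ship; the registry is an ordinary dict and extensible. Molecular ions
[M]⁺ and multiply charged species are out of scope. Displayed masses are
rounded half-away-from-zero to 4 decimal places; comparisons use
±0.0001 Da so a value sitting on a rounding boundary (CHF₃O₃S computes
to 149.95985) agrees with its 4-dp printed form.

## Filter cascade

Stages run in a fixed order — intensity, replicate RSD, blank ratio,
peak quality, componentization, MS² assembly — and each stage can only
remove features (a property test asserts the subset relation and the
recorded stage order).

Conventions where the operating point needed a decision:

- **Intensity** is inclusive (max replicate intensity ≥ threshold);
  **blank ratio** is strict (best sample mean > 3 × blank mean), reading
  "threshold" as attainable and "exceed by a factor of 3" as strict.
- **RSD** uses the sample standard deviation (n−1). "Present in the
  triplicates" is interpreted per sample: a feature survives if *any*
  sample has it in every replicate within 50% RSD — detection
  frequencies below 100% across samples are normal, so requiring all
  samples would be wrong.
- The RSD filter operates on raw, not blank-subtracted, intensities.
- The 0.4 Da precursor and 5 s RT windows for MS² assembly are **full
  widths** (±0.2 Da, ±2.5 s), matching quadrupole isolation-width
  convention. This is worth flagging: treating them as half-widths
  doubles the collection window.
- MS² merging normalizes each spectrum to base peak 100, averages within
  a collision energy, clusters fragment m/z across energies within
  ±5 mDa (greedy, running-mean centers), then averages relative
  intensities over the number of energies — a fragment absent at an
  energy contributes zero. Fragments averaging > 5% survive.
- The EIC peak-quality stage is a pluggable classifier interface. The
  shipped default is a transparent heuristic (≥ 5 points above
  half-maximum and a single local maximum); neural-network classifiers
  trained on real EICs can be plugged in unchanged. Features with no EIC
  trace pass with a warning rather than being silently dropped.
- Componentization is delta-mass/RT grouping: co-eluting partners
  (|ΔRT| ≤ 5 s) whose m/z difference matches a known adduct or isotope
  delta (¹³C 1.003355, Na−H 21.981944, NH₄−H 17.026549, K−H 37.955882;
  ±2 mDa) collapse onto the lighter member, keeping the
  protonated/deprotonated species. Full isotope-pattern scoring is out
  of scope.

## Suspect screening and the RTI filter

Suspects expand to [M+H]⁺ in positive mode and to [M−H]⁻ plus [M+Cl]⁻ in
negative mode; matching is inclusive at ±2 mDa (with a 1e-12 Da epsilon
guarding the boundary against binary rounding). Multi-matched features
are never discarded — every candidate is carried with flags, and the RT
filter arbitrates.

The retention-index model is an ordinary least-squares fit of RTI on
measured RT over the calibrants (scipy's linregress); predicting a
suspect's RT inverts the line. The fit direction (RTI ~ RT, then invert)
was chosen because calibrant RTI values are given and measured RT is the
noisy axis at prediction time. The plausibility window is ±120 s,
inclusive, in seconds — an equivalent RTI-units window would depend on
the data-specific slope, so the time window is authoritative. Suspects
without an RTI pass the filter flagged (prediction unset) so that list
coverage gaps do not silently drop candidates.

## Consensus annotation

The cosine score pairs fragments greedily by descending intensity
product within ±5 mDa (configurable; the tolerance is a choice, not a
published value), with unmatched peaks contributing to the norms. On
spectra whose peaks have at most one in-tolerance partner — the realistic
case at 5 mDa — greedy pairing equals the optimal assignment, and a test
verifies both this and agreement with matchms's CosineGreedy.

Clause order: (a) a library candidate with cosine > 0.5 and ≥ 3 matched
peaks wins at Level 2b; (b) otherwise, if the forward and inverse
in-silico top candidates each match ≥ 3 peaks and their fingerprints
have Tanimoto > 0.8, the better-supported engine's structure (more
matched peaks; forward wins ties) is assigned at Level 3; (c) otherwise
a single unambiguous formula gives Level 4; (d) otherwise Level 5.
Library-first ordering resolves the ambiguity of "highest score wins"
across engines whose native scores are incommensurable: within-source
ranking plus the cross-engine Tanimoto agreement gate replaces any
cross-scale comparison. Level 5 is included for unannotated features for
completeness of the Schymanski scheme. "> 2 matched peaks" is read as
strictly greater (≥ 3). Tanimoto of two all-zero fingerprints is defined
as 1 (identical absence of bits).

## Quantification and priority

Response factors are least-squares slopes of area on concentration (µM)
through the origin — a blank should give zero area, and an intercept
would let noise at the low levels leak into the slope. Concentrations
convert from ng/mL via the monoisotopic mass (for defined small
molecules the difference from average molar mass is far below the
method's accuracy). Curves with fewer than 5 detected levels are
rejected, as are non-positive slopes.

The ionization-efficiency transfer is OLS of log₁₀(RF) on predicted
logIE over the accepted calibrants; a feature's concentration is then
area / 10^(s·logIE + c), computed in µM and reported in mM. The toxicity
predictor is an interface (structure id → LC₅₀ in mM) with two shipped
implementations: a lookup table for known chemicals and a constant
baseline. Training ionization-efficiency or toxicity models is out of
scope; the workflow consumes their predictions.

Priority = concentration / LC₅₀ (both mM). Ranking is descending score;
ties break toward lower LC₅₀ (more toxic first), then feature id, making
the order total and permutation-invariant. Records with a predicted LC₅₀
but no concentration (e.g. negative-mode features where quantification
is unavailable) rank after scored records, ordered by ascending LC₅₀.
The score compares features to one another; it is not an absolute hazard
or risk estimate.

## Validation convention

A mis-annotated feature increments **both** FN ("not correctly
annotated") and FP ("a wrong structure was asserted"); an unannotated
feature is FN only. This differs from the textbook confusion matrix —
under it TP + FN equals the evaluable universe, TPR is the fraction of
evaluable features correctly annotated, and precision is the fraction of
asserted structures that are correct. Report rounding is half away from
zero to 2 dp (so 17/21 = 0.8095 prints 0.81); detection frequencies
round to whole percent.

## Synthetic data: what it shows and what it cannot

The generator emulates the target study design: 13 samples in triplicate
plus method blanks, a 38-chemical spiked mixture, a ten-level 1–1000
ng/mL calibration series, log-linear ESI response
RF = 10^(0.8·logIE + 3) with logIE ~ N(2, 1), retention times from a
latent hydrophobicity scale mapped onto a 60–1400 s gradient, RTI
= 0.5·RT + 10, LC₅₀ ~ 10^N(−0.7, 0.4) mM, and DDA spectra at 30/70/120 V
whose fragment intensities vary log-linearly with energy. Defaults are
noise-free so truth-recovery tests are exact; noise knobs (log-normal
replicate and calibration noise, m/z jitter, RTI jitter) exist for
robustness tests. Five calibration chemicals are left with only four
levels to exercise the minimum-level rejection. One root seed is
stream-split per component, so identical config + seed reproduces a
bundle byte-for-byte.

Each feature carries exactly one intended fate — pass, fail a named
filter, or collapse during componentization — and fragment sets are kept
pairwise disjoint (≥ 10 mDa) so decoy library scores stay below 0.5 by
construction; background and decoy masses are kept ≥ 4 mDa from every
real ion so truth labels cannot blur.

Passing these tests shows the pipeline's logic is faithful to its
contracts: stages remove exactly the features constructed to fail them,
screening recall is 1.0 on noise-free truth, annotation clauses fire as
constructed, and concentrations round-trip within 1%. It does **not**
show performance on real data, where peak shapes, co-elution, matrix
effects, fragmentation chemistry, and predictor errors (logIE, LC₅₀) are
far richer than the generative model: realistic fragmentation and
matrix-effect simulation are explicit non-goals. Problem sizes in the
default suite (~100 features, 38 chemicals, ≤ 200-feature oracle
comparisons) were chosen as the smallest instances that exercise every
code path.

## Known limitations

- Peak picking/alignment from raw data (mzML) is upstream and out of
  scope; the pipeline starts at aligned feature tables.
- Componentization is pairwise delta matching, not full isotope-pattern
  deconvolution; unusual adducts need registry entries.
- The RTI model is linear; strongly non-linear gradients would need a
  different calibration form.
- Uncertainty is not propagated through concentration or toxicity
  predictions; the priority score is a point estimate used only for
  relative ranking.
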