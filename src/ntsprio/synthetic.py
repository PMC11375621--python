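"""Seeded generator of complete, truth-labeled synthetic screening
experiments.

The generator emulates the study design the pipeline targets: triplicate
textile-extract samples plus method blanks measured by LC-ESI-HRMS in both
polarities, a spiked QC mixture with a ten-level calibration series
(1-1000 ng/mL), log-linear electrospray response (RF = 10^(a*logIE + b)),
retention times drawn from a latent hydrophobicity scale, DDA fragment
spectra at three collision energies, a suspect list carrying retention
time indices, and per-feature candidate tables mimicking external
annotation engines. Every generated feature carries an intended fate
(pass, fail a named filter, or be collapsed during componentization) so
each pipeline stage can be checked against construction.

One root seed is stream-split per component (chemicals, features,
spectra, suspects, candidates, calibration), so adding draws to one
component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationCandidate, LibrarySpectrum
from .chem import ADDUCTS, MolecularFormula, adduct_mz, monoisotopic_mass
from .features import ExperimentDesign, Feature, MS2Spectrum, assemble_ms2
from .prioritize import CalibrationCurve
from .suspects import SuspectEntry

__all__ = [
    "SyntheticConfig",
    "SyntheticChemical",
    "TruthBundle",
    "CalibrationTruth",
    "simulate_experiment",
    "simulate_calibration",
    "simulate_spectra",
]

FATES = (
    "pass",
    "fail_intensity",
    "fail_rsd",
    "fail_blank",
    "fail_quality",
    "component_drop",
)

ANNOTATION_ROUTES = ("2b", "3", "4", "5")

COLLISION_ENERGIES = (30.0, 70.0, 120.0)


@dataclass
class SyntheticConfig:
    """Knobs of the generative model; defaults mirror the emulated study
    (13 samples in triplicate with method blanks, a 38-chemical QC mixture,
    ten calibration levels spanning 1-1000 ng/mL)."""

    n_samples: int = 13
    n_replicates: int = 3
    n_blanks: int = 3
    n_spiked_chemicals: int = 38
    n_background_features: int = 40
    n_noise_features: int = 30
    calibration_levels: Tuple[float, ...] = (
        1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0,
    )
    n_calibration_low_sensitivity: int = 5  # chemicals left with <5 levels
    intensity_log_sigma: float = 0.0  # log-normal replicate noise
    calib_noise_sigma: float = 0.0  # log-normal area noise on curves
    mz_noise_mda: float = 0.0  # measured-m/z jitter (s.d., mDa)
    blank_carryover: float = 0.05
    positive_fraction: float = 0.7
    log_ie_mean: float = 2.0
    log_ie_sigma: float = 1.0
    ie_slope: float = 0.8  # log10(RF) = ie_slope * logIE + ie_intercept
    ie_intercept: float = 3.0
    log10_lc50_mean: float = -0.7  # LC50 in mM, log10 scale
    log10_lc50_sigma: float = 0.4
    rti_slope: float = 0.5  # RTI per second
    rti_intercept: float = 10.0
    rti_jitter_sigma: float = 0.0
    suspect_fraction: float = 1.0  # spiked chemicals carried on the list
    n_decoy_suspects: int = 15
    rt_range: Tuple[float, float] = (60.0, 1400.0)  # seconds
    fingerprint_bits: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_samples, self.n_replicates, self.n_blanks,
            self.n_spiked_chemicals, self.n_background_features,
            self.n_noise_features, self.n_decoy_suspects,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not 0 <= self.suspect_fraction <= 1:
            raise ValueError("suspect_fraction must be in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates for the RSD filter")


@dataclass
class SyntheticChemical:
    """Ground-truth description of one spiked chemical."""

    name: str
    formula: MolecularFormula
    mass: float
    polarity: str
    adduct_name: str
    rt: float
    rti: float
    log_ie: float
    lc50_mm: float
    conc_mm: float
    fragments: List[Tuple[float, float, float]]  # (mz, base weight, energy slope)
    fingerprint: np.ndarray
    in_suspect_list: bool = True
    annotation_route: str = "2b"

    @property
    def ion_mz(self) -> float:
        return adduct_mz(self.mass, ADDUCTS[self.adduct_name])


@dataclass
class CalibrationTruth:
    curves: List[CalibrationCurve]
    true_rfs: Dict[str, float]
    log_ie: Dict[str, float]
    n_levels: Dict[str, int]


@dataclass
class TruthBundle:
    """Everything the pipeline consumes plus the generating truth."""

    config: SyntheticConfig
    chemicals: List[SyntheticChemical]
    design: ExperimentDesign
    features: List[Feature]
    eics: Dict[str, np.ndarray]
    spectra: List[MS2Spectrum]
    library: List[LibrarySpectrum]
    suspects: List[SuspectEntry]
    candidates: Dict[str, List[AnnotationCandidate]]
    rti_calibrants: List[Tuple[float, float]]
    calibration: CalibrationTruth
    truth: pd.DataFrame
    ie_slope: float
    ie_intercept: float


def _random_formula(rng: np.random.Generator) -> MolecularFormula:
    counts = {"C": int(rng.integers(6, 28))}
    counts["H"] = int(rng.integers(counts["C"], 2 * counts["C"] + 2))
    for el, p, hi in (("O", 0.85, 8), ("N", 0.5, 4), ("S", 0.2, 2), ("Cl", 0.15, 2)):
        if rng.random() < p:
            counts[el] = int(rng.integers(1, hi + 1))
    return MolecularFormula(counts)


def _random_fingerprint(rng: np.random.Generator, n_bits: int) -> np.ndarray:
    return rng.random(n_bits) < 0.25


def _make_fragments(
    rng: np.random.Generator, precursor_mz: float, k: int = 8
) -> List[Tuple[float, float, float]]:
    """Fragment set: (m/z, base relative weight, energy slope). One
    fragment is forced below the 5% relative-intensity floor so spectrum
    pruning is exercised."""
    mzs = np.sort(rng.uniform(50.0, max(60.0, precursor_mz - 20.0), size=k))
    raw = rng.dirichlet(np.ones(k))
    weights = 15.0 + 85.0 * raw / raw.max()  # every real fragment >= 15%
    weights[int(rng.integers(0, k))] = rng.uniform(1.0, 3.0)  # sub-5% peak
    slopes = rng.normal(0.0, 0.3, size=k)
    return [(float(m), float(w), float(s)) for m, w, s in zip(mzs, weights, slopes)]


def simulate_spectra(
    chemical: SyntheticChemical,
    energies: Sequence[float] = COLLISION_ENERGIES,
    seed: Optional[int] = None,
    scale: float = 1e4,
    noise_sigma: float = 0.0,
) -> List[MS2Spectrum]:
    """Per-energy DDA spectra for one chemical. Fragment intensities vary
    smoothly with collision energy via per-fragment log-linear slopes."""
    rng = np.random.default_rng(seed)
    out = []
    for energy in energies:
        peaks = []
        for mz, base, slope in chemical.fragments:
            rel = base * float(np.exp(slope * (energy - 70.0) / 50.0))
            if noise_sigma > 0:
                rel *= float(np.exp(rng.normal(0.0, noise_sigma)))
            peaks.append((mz, max(rel, 1e-6) * scale / 100.0))
        out.append(MS2Spectrum(chemical.ion_mz, chemical.rt, float(energy), peaks))
    return out


def _make_design(config: SyntheticConfig) -> ExperimentDesign:
    samples = {
        f"S{i + 1:02d}": [f"S{i + 1:02d}_r{j + 1}" for j in range(config.n_replicates)]
        for i in range(config.n_samples)
    }
    blanks = [f"B{j + 1}" for j in range(config.n_blanks)]
    return ExperimentDesign(samples=samples, blanks=blanks)


def _gaussian_eic(rng: np.random.Generator, n: int = 20) -> np.ndarray:
    x = np.linspace(-2.5, 2.5, n)
    return np.exp(-0.5 * x**2) * 1e5


def _spike_eic() -> np.ndarray:
    return np.array([0.0, 1e5])


def _replicate_intensities(
    rng: np.random.Generator,
    design: ExperimentDesign,
    detected_samples: Sequence[str],
    base_area: float,
    log_sigma: float,
    blank_carryover: float,
) -> Dict[str, float]:
    intensities: Dict[str, float] = {}
    for sample in detected_samples:
        for rep in design.samples[sample]:
            noise = float(np.exp(rng.normal(0.0, log_sigma))) if log_sigma > 0 else 1.0
            intensities[rep] = base_area * noise
    if blank_carryover > 0:
        for rep in design.blanks:
            intensities[rep] = base_area * blank_carryover
    return intensities


def _resolve_mz_conflicts(mz: float, taken: List[float], rng: np.random.Generator) -> float:
    """Keep decoy/background masses at least 4 mDa from every known ion so
    accidental suspect matches cannot blur truth labels."""
    while any(abs(mz - t) < 0.004 for t in taken):
        mz += rng.uniform(0.01, 0.05)
    return mz


def simulate_experiment(config: SyntheticConfig, seed: Optional[int] = None) -> TruthBundle:
    """Generate a full truth-labeled experiment bundle."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    (ss_chem, ss_feat, ss_spec, ss_susp, ss_cand, ss_calib) = root.spawn(6)
    rng_chem = np.random.default_rng(ss_chem)
    rng_feat = np.random.default_rng(ss_feat)
    rng_susp = np.random.default_rng(ss_susp)
    rng_cand = np.random.default_rng(ss_cand)

    design = _make_design(config)
    rt_lo, rt_hi = config.rt_range

    # --- chemicals -------------------------------------------------------
    chemicals: List[SyntheticChemical] = []
    spec_seeds = ss_spec.generate_state(max(config.n_spiked_chemicals, 1) * 2)
    for i in range(config.n_spiked_chemicals):
        formula = _random_formula(rng_chem)
        mass = monoisotopic_mass(formula)
        while not (100.0 + 2 < mass < 1500.0 - 36):
            formula = _random_formula(rng_chem)
            mass = monoisotopic_mass(formula)
        polarity = "positive" if rng_chem.random() < config.positive_fraction else "negative"
        adduct_name = "[M+H]+" if polarity == "positive" else "[M-H]-"
        hydrophobicity = float(rng_chem.uniform(0.0, 1.0))
        rt = rt_lo + hydrophobicity * (rt_hi - rt_lo)
        rti = (
            config.rti_slope * rt
            + config.rti_intercept
            + (rng_chem.normal(0.0, config.rti_jitter_sigma) if config.rti_jitter_sigma > 0 else 0.0)
        )
        chem = SyntheticChemical(
            name=f"chem_{i + 1:03d}",
            formula=formula,
            mass=mass,
            polarity=polarity,
            adduct_name=adduct_name,
            rt=rt,
            rti=float(rti),
            log_ie=float(rng_chem.normal(config.log_ie_mean, config.log_ie_sigma)),
            lc50_mm=float(10.0 ** rng_chem.normal(config.log10_lc50_mean, config.log10_lc50_sigma)),
            conc_mm=float(10.0 ** rng_chem.uniform(-3.0, 0.0)),
            fragments=[],
            fingerprint=_random_fingerprint(rng_chem, config.fingerprint_bits),
            in_suspect_list=bool(rng_chem.random() < config.suspect_fraction),
            annotation_route=ANNOTATION_ROUTES[i % 3],  # cycle 2b / 3 / 4
        )
        chem.fragments = _make_fragments(rng_chem, chem.ion_mz)
        chemicals.append(chem)

    # keep fragment sets pairwise disjoint (>=10 mDa apart) so decoy
    # library entries score near zero by construction
    seen_frags: List[float] = []
    for chem in chemicals:
        fixed = []
        for mz, w, s in chem.fragments:
            while any(abs(mz - f) < 0.010 for f in seen_frags):
                mz += float(rng_chem.uniform(0.02, 0.08))
            seen_frags.append(mz)
            fixed.append((mz, w, s))
        chem.fragments = sorted(fixed)

    # --- features --------------------------------------------------------
    thresholds = {"positive": 100_000.0, "negative": 50_000.0}
    features: List[Feature] = []
    eics: Dict[str, np.ndarray] = {}
    truth_rows: List[Dict[str, object]] = []
    taken_mz: List[float] = [c.ion_mz for c in chemicals]

    def add_truth(feature: Feature, fate: str, chemical: Optional[str],
                  conc: Optional[float], lc50: Optional[float],
                  log_ie: Optional[float], in_list: bool, route: Optional[str],
                  n_detected: int) -> None:
        truth_rows.append(
            {
                "feature_id": feature.id,
                "chemical": chemical,
                "fate": fate,
                "polarity": feature.polarity,
                "mz": feature.mz,
                "rt": feature.rt,
                "true_conc_mM": conc,
                "lc50_mM": lc50,
                "log_ie": log_ie,
                "in_suspect_list": in_list,
                "expected_level": route,
                "n_detected_samples": n_detected,
            }
        )

    sample_ids = list(design.samples)
    for i, chem in enumerate(chemicals):
        rf = 10.0 ** (config.ie_slope * chem.log_ie + config.ie_intercept)
        base_area = rf * chem.conc_mm * 1000.0  # conc in uM
        if base_area < 1.2 * thresholds[chem.polarity]:
            chem.conc_mm = 1.2 * thresholds[chem.polarity] / (rf * 1000.0)
            base_area = rf * chem.conc_mm * 1000.0
        n_det = int(rng_feat.integers(1, config.n_samples + 1))
        detected = list(rng_feat.choice(sample_ids, size=n_det, replace=False))
        mz = chem.ion_mz
        if config.mz_noise_mda > 0:
            mz += float(rng_feat.normal(0.0, config.mz_noise_mda / 1000.0))
        feature = Feature(
            id=f"f_spk_{i + 1:03d}",
            mz=mz,
            rt=chem.rt,
            polarity=chem.polarity,
            intensities=_replicate_intensities(
                rng_feat, design, detected, base_area,
                config.intensity_log_sigma, config.blank_carryover,
            ),
        )
        features.append(feature)
        eics[feature.id] = _gaussian_eic(rng_feat)
        add_truth(feature, "pass", chem.name, chem.conc_mm, chem.lc50_mm,
                  chem.log_ie, chem.in_suspect_list, chem.annotation_route, n_det)

    for i in range(config.n_background_features):
        polarity = "positive" if rng_feat.random() < config.positive_fraction else "negative"
        mz = _resolve_mz_conflicts(float(rng_feat.uniform(100.0, 1000.0)), taken_mz, rng_feat)
        taken_mz.append(mz)
        rt = float(rng_feat.uniform(rt_lo, rt_hi))
        base = thresholds[polarity] * float(rng_feat.uniform(2.0, 50.0))
        n_det = int(rng_feat.integers(1, config.n_samples + 1))
        detected = list(rng_feat.choice(sample_ids, size=n_det, replace=False))
        feature = Feature(
            id=f"f_bkg_{i + 1:03d}", mz=mz, rt=rt, polarity=polarity,
            intensities=_replicate_intensities(
                rng_feat, design, detected, base,
                config.intensity_log_sigma, config.blank_carryover,
            ),
        )
        features.append(feature)
        eics[feature.id] = _gaussian_eic(rng_feat)
        add_truth(feature, "pass", None, None, None, None, False, "5", n_det)

    droppable = [f for f in features]  # passing features eligible as partners
    fail_fates = ("fail_intensity", "fail_rsd", "fail_blank", "fail_quality", "component_drop")
    for i in range(config.n_noise_features):
        fate = fail_fates[i % len(fail_fates)]
        polarity = "positive" if rng_feat.random() < config.positive_fraction else "negative"
        fid = f"f_noise_{i + 1:03d}"
        sample = sample_ids[int(rng_feat.integers(0, len(sample_ids)))]
        reps = design.samples[sample]
        threshold = thresholds[polarity]
        if fate == "component_drop":
            partner = droppable[int(rng_feat.integers(0, len(droppable)))]
            delta = 21.981944 if rng_feat.random() < 0.5 else 1.003355
            feature = Feature(
                id=fid, mz=partner.mz + delta, rt=partner.rt, polarity=partner.polarity,
                intensities={
                    r: v for r, v in partner.intensities.items()
                    if r not in design.blanks
                },
            )
            eics[feature.id] = _gaussian_eic(rng_feat)
        elif fate == "fail_intensity":
            base = threshold * float(rng_feat.uniform(0.2, 0.8))
            feature = Feature(
                id=fid, mz=_resolve_mz_conflicts(float(rng_feat.uniform(100.0, 1000.0)), taken_mz, rng_feat),
                rt=float(rng_feat.uniform(rt_lo, rt_hi)), polarity=polarity,
                intensities={r: base for r in reps},
            )
            eics[feature.id] = _gaussian_eic(rng_feat)
        elif fate == "fail_rsd":
            base = threshold * 2.0
            feature = Feature(
                id=fid, mz=_resolve_mz_conflicts(float(rng_feat.uniform(100.0, 1000.0)), taken_mz, rng_feat),
                rt=float(rng_feat.uniform(rt_lo, rt_hi)), polarity=polarity,
                intensities={r: base * (1.0 + 4.0 * j) for j, r in enumerate(reps)},
            )
            eics[feature.id] = _gaussian_eic(rng_feat)
        elif fate == "fail_blank":
            base = threshold * 4.0
            intens = {r: base for r in reps}
            intens.update({b: base / 2.0 for b in design.blanks})
            feature = Feature(
                id=fid, mz=_resolve_mz_conflicts(float(rng_feat.uniform(100.0, 1000.0)), taken_mz, rng_feat),
                rt=float(rng_feat.uniform(rt_lo, rt_hi)), polarity=polarity,
                intensities=intens,
            )
            eics[feature.id] = _gaussian_eic(rng_feat)
        else:  # fail_quality
            base = threshold * 4.0
            feature = Feature(
                id=fid, mz=_resolve_mz_conflicts(float(rng_feat.uniform(100.0, 1000.0)), taken_mz, rng_feat),
                rt=float(rng_feat.uniform(rt_lo, rt_hi)), polarity=polarity,
                intensities={r: base for r in reps},
            )
            eics[feature.id] = _spike_eic()
        taken_mz.append(feature.mz)
        features.append(feature)
        add_truth(feature, fate, None, None, None, None, False, None, 1)

    # --- spectra + library ----------------------------------------------
    spectra: List[MS2Spectrum] = []
    library: List[LibrarySpectrum] = []
    for i, chem in enumerate(chemicals):
        chem_spectra = simulate_spectra(chem, COLLISION_ENERGIES, int(spec_seeds[i]))
        spectra.extend(chem_spectra)
        if chem.annotation_route == "2b":
            probe = Feature(id="probe", mz=chem.ion_mz, rt=chem.rt,
                            polarity=chem.polarity, intensities={})
            reference = assemble_ms2(probe, chem_spectra)
            if reference is not None:
                library.append(
                    LibrarySpectrum(chem.name, reference, name=chem.name,
                                    formula=chem.formula.hill())
                )

    # --- suspect list ----------------------------------------------------
    suspects: List[SuspectEntry] = []
    for chem in chemicals:
        if chem.in_suspect_list:
            suspects.append(
                SuspectEntry(
                    name=chem.name, formula=chem.formula, rti=chem.rti,
                    exposure_score=int(rng_susp.integers(1, 26)), source="SYN-LIST",
                )
            )
    for i in range(config.n_decoy_suspects):
        mass = float(rng_susp.uniform(120.0, 900.0))
        # keep every possible decoy ion >=4 mDa from all real feature ions
        shifts = (1.007276, -1.007276, 34.969402)
        while any(
            abs((mass + s) - t) < 0.004 for s in shifts for t in taken_mz
        ):
            mass += float(rng_susp.uniform(0.01, 0.05))
        taken_mz.extend(mass + s for s in shifts)
        suspects.append(
            SuspectEntry(
                name=f"decoy_{i + 1:03d}", exact_mass=mass,
                rti=float(rng_susp.uniform(
                    config.rti_intercept + config.rti_slope * rt_lo,
                    config.rti_intercept + config.rti_slope * rt_hi,
                )),
                exposure_score=int(rng_susp.integers(1, 26)), source="SYN-LIST",
            )
        )

    # --- candidate tables (external-engine stand-ins) --------------------
    candidates: Dict[str, List[AnnotationCandidate]] = {}
    for i, chem in enumerate(chemicals):
        fid = f"f_spk_{i + 1:03d}"
        cands: List[AnnotationCandidate] = []
        n_frag = sum(1 for _, w, _ in chem.fragments if w > 5.0)
        if chem.annotation_route in ("2b", "3"):
            decoy_fp = _random_fingerprint(rng_cand, config.fingerprint_bits)
            cands.append(
                AnnotationCandidate(chem.name, "silico_forward", 0.95,
                                    matched_peaks=max(n_frag, 3),
                                    fingerprint=chem.fingerprint)
            )
            cands.append(
                AnnotationCandidate(f"decoy_of_{chem.name}", "silico_forward", 0.40,
                                    matched_peaks=1, fingerprint=decoy_fp)
            )
            cands.append(
                AnnotationCandidate(chem.name, "silico_inverse", 0.90,
                                    matched_peaks=max(n_frag, 3),
                                    fingerprint=chem.fingerprint.copy())
            )
            cands.append(AnnotationCandidate(chem.formula.hill(), "formula_only", 1.0))
        else:  # route 4: engines fail to agree; formula is unequivocal
            cands.append(
                AnnotationCandidate(chem.name, "silico_forward", 0.6,
                                    matched_peaks=1, fingerprint=chem.fingerprint)
            )
            cands.append(
                AnnotationCandidate(
                    f"decoy_of_{chem.name}", "silico_inverse", 0.55, matched_peaks=1,
                    fingerprint=_random_fingerprint(rng_cand, config.fingerprint_bits),
                )
            )
            cands.append(AnnotationCandidate(chem.formula.hill(), "formula_only", 1.0))
        candidates[fid] = cands

    calibration = simulate_calibration(config, seed, chemicals=chemicals)
    rti_calibrants = [(c.rt, c.rti) for c in chemicals]

    return TruthBundle(
        config=config,
        chemicals=chemicals,
        design=design,
        features=features,
        eics=eics,
        spectra=spectra,
        library=library,
        suspects=suspects,
        candidates=candidates,
        rti_calibrants=rti_calibrants,
        calibration=calibration,
        truth=pd.DataFrame(truth_rows),
        ie_slope=config.ie_slope,
        ie_intercept=config.ie_intercept,
    )


def simulate_calibration(
    config: SyntheticConfig,
    seed: Optional[int] = None,
    chemicals: Optional[Sequence[SyntheticChemical]] = None,
) -> CalibrationTruth:
    """Ten-level calibration curves with true response factors.

    A configured number of low-sensitivity chemicals keep only their four
    highest levels, exercising the minimum-level rejection downstream.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rng = np.random.default_rng(root.spawn(7)[6])
    if chemicals is None:
        chemicals = simulate_experiment(config, seed).chemicals
    curves: List[CalibrationCurve] = []
    true_rfs: Dict[str, float] = {}
    log_ie: Dict[str, float] = {}
    n_levels: Dict[str, int] = {}
    for i, chem in enumerate(chemicals):
        rf = 10.0 ** (config.ie_slope * chem.log_ie + config.ie_intercept)
        mw = monoisotopic_mass(chem.formula)
        levels = []
        usable = (
            sorted(config.calibration_levels)[-4:]
            if i < config.n_calibration_low_sensitivity
            else config.calibration_levels
        )
        for conc_ng_ml in usable:
            conc_um = conc_ng_ml / mw
            noise = (
                float(np.exp(rng.normal(0.0, config.calib_noise_sigma)))
                if config.calib_noise_sigma > 0
                else 1.0
            )
            levels.append((float(conc_ng_ml), rf * conc_um * noise))
        curves.append(CalibrationCurve(chem.name, chem.formula, levels))
        true_rfs[chem.name] = rf
        log_ie[chem.name] = chem.log_ie
        n_levels[chem.name] = len(levels)
    return CalibrationTruth(curves, true_rfs, log_ie, n_levels)
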