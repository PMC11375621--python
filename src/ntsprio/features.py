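"""Quality-filter cascade for aligned LC-HRMS feature tables.

Raw aligned features pass through, in order: an intensity threshold,
a replicate-reproducibility (RSD) filter, a blank-ratio filter, an
EIC peak-quality check, componentization (adduct/isotope collapse), and
MS2 spectrum assembly. Each stage only ever removes features; the
:class:`FilterTrace` records the funnel.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "ExperimentDesign",
    "MS2Spectrum",
    "FilterTrace",
    "CascadeConfig",
    "CascadeResult",
    "DEFAULT_INTENSITY_THRESHOLDS",
    "ADDUCT_ISOTOPE_DELTAS",
    "filter_intensity",
    "filter_replicate_rsd",
    "filter_blank_ratio",
    "classify_peak_quality",
    "componentize",
    "assemble_ms2",
    "run_cascade",
]

MZ_RANGE = (100.0, 1500.0)  # acquisition range of the MS1 scan

DEFAULT_INTENSITY_THRESHOLDS: Dict[str, float] = {
    "positive": 100_000.0,
    "negative": 50_000.0,
}

# m/z deltas (Da) relative to the protonated/deprotonated species that mark
# a co-eluting feature as a non-preserved adduct or isotope peak.
ADDUCT_ISOTOPE_DELTAS: Dict[str, float] = {
    "13C": 1.003355,
    "Na-H": 21.981944,
    "NH4-H": 17.026549,
    "K-H": 37.955882,
}


@dataclass
class Feature:
    """One aligned LC-HRMS ion across all sample replicates.

    ``intensities`` maps replicate id -> abundance; a missing key means the
    feature was not detected in that injection.
    """

    id: str
    mz: float
    rt: float
    polarity: str
    intensities: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"feature {self.id}: invalid polarity {self.polarity!r}")
        if self.rt < 0:
            raise ValueError(f"feature {self.id}: negative retention time")

    def max_intensity(self) -> float:
        return max(self.intensities.values(), default=0.0)


@dataclass
class ExperimentDesign:
    """Sample/replicate layout: sample id -> replicate ids, plus blank ids."""

    samples: Dict[str, List[str]]
    blanks: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set = set()
        for sample, reps in self.samples.items():
            for rep in reps:
                if rep in seen:
                    raise ValueError(f"duplicate replicate id {rep!r}")
                seen.add(rep)
        for rep in self.blanks:
            if rep in seen:
                raise ValueError(f"blank replicate id {rep!r} reused")
            seen.add(rep)

    @property
    def replicate_ids(self) -> List[str]:
        out = [r for reps in self.samples.values() for r in reps]
        return out + list(self.blanks)

    @property
    def replicate_count(self) -> int:
        return max((len(r) for r in self.samples.values()), default=0)


@dataclass
class MS2Spectrum:
    """A fragment spectrum: precursor m/z, RT, collision energy, peak list."""

    precursor_mz: float
    rt: float
    collision_energy: Optional[float]
    peaks: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError("fragment intensities must be positive")

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def normalized(self) -> "MS2Spectrum":
        """Scale so the base peak is 100."""
        base = max((i for _, i in self.peaks), default=0.0)
        if base == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return MS2Spectrum(
            self.precursor_mz,
            self.rt,
            self.collision_energy,
            [(m, i / base * 100.0) for m, i in self.peaks],
        )


@dataclass
class FilterTrace:
    """Per-stage (features_in, features_out) funnel record."""

    stages: List[Tuple[str, int, int]] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage!r} gained features ({n_in} -> {n_out})")
        self.stages.append((stage, n_in, n_out))

    def stage_names(self) -> List[str]:
        return [s for s, _, _ in self.stages]

    def as_rows(self) -> List[Dict[str, object]]:
        total = self.stages[0][1] if self.stages else 0
        rows = []
        for stage, n_in, n_out in self.stages:
            rows.append(
                {
                    "stage": stage,
                    "features_in": n_in,
                    "features_out": n_out,
                    "pct_of_input": round(100.0 * n_out / total, 1) if total else 0.0,
                }
            )
        return rows


def filter_intensity(
    features: Sequence[Feature],
    thresholds: Optional[Mapping[str, float]] = None,
) -> List[Feature]:
    """Keep features whose maximum replicate intensity reaches the
    polarity-specific threshold (inclusive)."""
    thresholds = dict(thresholds) if thresholds else dict(DEFAULT_INTENSITY_THRESHOLDS)
    kept = []
    for f in features:
        if f.polarity not in thresholds:
            raise ValueError(f"feature {f.id}: no threshold for polarity {f.polarity!r}")
        if f.max_intensity() >= thresholds[f.polarity]:
            kept.append(f)
    return kept


def _sample_rsd(values: Sequence[float]) -> float:
    mean = float(np.mean(values))
    if mean == 0:
        return math.inf
    return 100.0 * float(np.std(values, ddof=1)) / mean


def filter_replicate_rsd(
    features: Sequence[Feature],
    design: ExperimentDesign,
    max_rsd_pct: float = 50.0,
) -> List[Feature]:
    """Keep features detected in every replicate of at least one sample with
    a relative standard deviation at or below ``max_rsd_pct``.

    The RSD uses the sample standard deviation (n-1 denominator).
    """
    if design.replicate_count < 2:
        raise ValueError("RSD filter needs at least 2 replicates per sample")
    kept = []
    for f in features:
        for reps in design.samples.values():
            vals = [f.intensities[r] for r in reps if r in f.intensities and f.intensities[r] > 0]
            if len(vals) == len(reps) and _sample_rsd(vals) <= max_rsd_pct:
                kept.append(f)
                break
    return kept


def filter_blank_ratio(
    features: Sequence[Feature],
    design: ExperimentDesign,
    factor: float = 3.0,
) -> List[Feature]:
    """Keep features whose best per-sample mean intensity strictly exceeds
    ``factor`` times the mean method-blank intensity (absent = 0)."""
    if factor <= 0:
        raise ValueError("blank factor must be positive")
    if not design.blanks:
        warnings.warn("no blanks in design; blank-ratio filter passes all features")
        return list(features)
    kept = []
    for f in features:
        blank_mean = float(np.mean([f.intensities.get(r, 0.0) for r in design.blanks]))
        best = max(
            float(np.mean([f.intensities.get(r, 0.0) for r in reps]))
            for reps in design.samples.values()
        )
        if best > factor * blank_mean:
            kept.append(f)
    return kept


QualityClassifier = Callable[[Feature, Optional[np.ndarray]], str]


def classify_peak_quality(
    feature: Feature,
    eic: Optional[np.ndarray] = None,
    classifier: Optional[QualityClassifier] = None,
) -> str:
    """Label a feature's chromatographic peak ``"high"`` or ``"low"`` quality.

    The default heuristic calls a peak high quality when its EIC trace has
    at least 5 points above half-maximum and a single local maximum.
    Features with no EIC data pass (with a warning) so that workflows
    lacking raw traces are not silently emptied. A ``classifier`` callable
    (feature, eic) -> label can replace the heuristic, e.g. to plug in a
    trained neural-network peak classifier.
    """
    if classifier is not None:
        try:
            return classifier(feature, eic)
        except Exception as exc:
            raise RuntimeError(f"peak-quality classifier failed on feature {feature.id}") from exc
    if eic is None:
        warnings.warn(f"feature {feature.id}: no EIC trace; passing quality check")
        return "high"
    trace = np.asarray(eic, dtype=float)
    if trace.size == 0 or trace.max() <= 0:
        return "low"
    above_half = int(np.sum(trace > trace.max() / 2.0))
    # count strict local maxima, collapsing plateaus
    peaks = 0
    rising = False
    for i in range(1, trace.size):
        if trace[i] > trace[i - 1]:
            rising = True
        elif trace[i] < trace[i - 1]:
            if rising or i == 1:
                peaks += 1
            rising = False
    if rising:  # monotone rise into the last point
        peaks += 1
    return "high" if above_half >= 5 and peaks == 1 else "low"


def componentize(
    features: Sequence[Feature],
    rt_tol: float = 5.0,
    adduct_deltas: Optional[Mapping[str, float]] = None,
    mz_tol_mda: float = 2.0,
) -> Tuple[List[Feature], Dict[str, str]]:
    """Collapse co-eluting adduct/isotope partners onto one representative.

    Co-eluting feature pairs (|dRT| <= ``rt_tol`` s) whose m/z difference
    matches a known delta within ``mz_tol_mda`` are grouped; the heavier
    member (the sodiated / isotopic peak) is dropped so only the
    protonated/deprotonated species survives. Singletons are kept.

    Returns (kept features, dropped feature id -> delta name).
    """
    deltas = dict(adduct_deltas) if adduct_deltas else dict(ADDUCT_ISOTOPE_DELTAS)
    tol = mz_tol_mda / 1000.0
    ordered = sorted(features, key=lambda f: f.mz)
    dropped: Dict[str, str] = {}
    for i, low in enumerate(ordered):
        if low.id in dropped:
            continue
        for high in ordered[i + 1 :]:
            if high.mz - low.mz > max(deltas.values()) + tol:
                break
            if high.id in dropped or abs(high.rt - low.rt) > rt_tol:
                continue
            for name, delta in deltas.items():
                if abs((high.mz - low.mz) - delta) <= tol:
                    dropped[high.id] = name
                    break
    kept = [f for f in features if f.id not in dropped]
    return kept, dropped


def _cluster_peaks(
    peaks: Sequence[Tuple[float, float]], tol: float
) -> List[List[Tuple[float, float]]]:
    """Greedy m/z clustering: consecutive peaks within ``tol`` of the
    cluster's running mean join it."""
    clusters: List[List[Tuple[float, float]]] = []
    for mz, inten in sorted(peaks):
        if clusters:
            ref = float(np.mean([m for m, _ in clusters[-1]]))
            if abs(mz - ref) <= tol:
                clusters[-1].append((mz, inten))
                continue
        clusters.append([(mz, inten)])
    return clusters


def assemble_ms2(
    feature: Feature,
    spectra: Sequence[MS2Spectrum],
    precursor_window: float = 0.4,
    rt_window: float = 5.0,
    min_rel_intensity: float = 5.0,
    frag_tol_mda: float = 5.0,
) -> Optional[MS2Spectrum]:
    """Merge the DDA spectra acquired for a feature across collision energies.

    ``precursor_window`` and ``rt_window`` are full widths (quadrupole
    isolation convention), so matching uses +/- half of each. Within each
    collision energy, spectra are normalized to base peak 100 and averaged;
    fragment m/z values are then clustered across energies within
    +/- ``frag_tol_mda`` and the relative intensities averaged over all
    energies (a fragment absent at an energy contributes 0). Fragments with
    averaged relative intensity strictly above ``min_rel_intensity`` are
    retained. Returns ``None`` if no spectrum matches.
    """
    matched = [
        s
        for s in spectra
        if abs(s.precursor_mz - feature.mz) <= precursor_window / 2.0
        and abs(s.rt - feature.rt) <= rt_window / 2.0
    ]
    if not matched:
        return None
    by_energy: Dict[Optional[float], List[MS2Spectrum]] = {}
    for s in matched:
        by_energy.setdefault(s.collision_energy, []).append(s.normalized())
    tol = frag_tol_mda / 1000.0
    energy_profiles: List[List[Tuple[float, float]]] = []
    for group in by_energy.values():
        pooled = [(m, i) for s in group for m, i in s.peaks]
        merged = [
            (float(np.mean([m for m, _ in cl])), float(np.mean([i for _, i in cl])))
            for cl in _cluster_peaks(pooled, tol)
        ]
        energy_profiles.append(merged)
    n_energies = len(energy_profiles)
    all_peaks = [(m, i) for prof in energy_profiles for m, i in prof]
    out = []
    for cl in _cluster_peaks(all_peaks, tol):
        avg = sum(i for _, i in cl) / n_energies
        if avg > min_rel_intensity:
            out.append((float(np.mean([m for m, _ in cl])), avg))
    if not out:
        return None
    return MS2Spectrum(feature.mz, feature.rt, None, out)


@dataclass
class CascadeConfig:
    """Thresholds for :func:`run_cascade`; defaults are the workflow's
    published operating point."""

    intensity_thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_THRESHOLDS)
    )
    max_rsd_pct: float = 50.0
    blank_factor: float = 3.0
    componentize_rt_tol: float = 5.0
    componentize_mz_tol_mda: float = 2.0
    precursor_window: float = 0.4
    rt_window: float = 5.0
    min_rel_intensity: float = 5.0
    frag_tol_mda: float = 5.0


@dataclass
class CascadeResult:
    features: List[Feature]
    spectra: Dict[str, MS2Spectrum]
    trace: FilterTrace
    dropped_components: Dict[str, str]


def run_cascade(
    features: Sequence[Feature],
    design: ExperimentDesign,
    config: Optional[CascadeConfig] = None,
    spectra: Optional[Sequence[MS2Spectrum]] = None,
    eics: Optional[Mapping[str, np.ndarray]] = None,
    classifier: Optional[QualityClassifier] = None,
) -> CascadeResult:
    """Apply the full filter cascade in its fixed order and assemble MS2.

    Stage order: intensity -> replicate RSD -> blank ratio -> peak quality
    -> componentization -> MS2 assembly.
    """
    cfg = config or CascadeConfig()
    trace = FilterTrace()
    current: List[Feature] = list(features)

    n_in = len(current)
    current = filter_intensity(current, cfg.intensity_thresholds)
    trace.record("intensity", n_in, len(current))

    n_in = len(current)
    if current:
        current = filter_replicate_rsd(current, design, cfg.max_rsd_pct)
    trace.record("replicate_rsd", n_in, len(current))

    n_in = len(current)
    if current:
        current = filter_blank_ratio(current, design, cfg.blank_factor)
    trace.record("blank_ratio", n_in, len(current))

    n_in = len(current)
    current = [
        f
        for f in current
        if classify_peak_quality(f, eics.get(f.id) if eics else None, classifier) == "high"
    ]
    trace.record("peak_quality", n_in, len(current))

    n_in = len(current)
    dropped_all: Dict[str, str] = {}
    kept: List[Feature] = []
    for pol in ("positive", "negative"):
        subset = [f for f in current if f.polarity == pol]
        kept_pol, dropped = componentize(
            subset, cfg.componentize_rt_tol, mz_tol_mda=cfg.componentize_mz_tol_mda
        )
        kept.extend(kept_pol)
        dropped_all.update(dropped)
    current = [f for f in current if f.id not in dropped_all]
    trace.record("componentization", n_in, len(current))

    assembled: Dict[str, MS2Spectrum] = {}
    if spectra:
        for f in current:
            merged = assemble_ms2(
                f,
                spectra,
                cfg.precursor_window,
                cfg.rt_window,
                cfg.min_rel_intensity,
                cfg.frag_tol_mda,
            )
            if merged is not None:
                assembled[f.id] = merged
    trace.record("ms2_assembly", len(current), len(current))

    for row in trace.as_rows():
        logger.info(
            "cascade %-16s %6d -> %6d (%.1f%%)",
            row["stage"],
            row["features_in"],
            row["features_out"],
            row["pct_of_input"],
        )
    return CascadeResult(current, assembled, trace, dropped_all)
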