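"""Suspect screening: adduct expansion, exact-mass matching and the
retention-time-index (RTI) plausibility filter.

Suspect lists (e.g. NORMAN Suspect List Exchange exports of textile-related
or PMT chemicals) provide formulas/exact masses and optionally an RTI on a
system-independent elution scale. Candidate ion m/z values are computed for
each applicable adduct, matched to measured features within a mDa
tolerance, and implausible matches are rejected by comparing observed RT
against the RT predicted from the suspect's RTI through a linear
calibration model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .chem import ADDUCTS, Adduct, MolecularFormula, adduct_mz, monoisotopic_mass
from .features import Feature

logger = logging.getLogger(__name__)

__all__ = [
    "SuspectEntry",
    "CandidateIon",
    "SuspectMatch",
    "RtiModel",
    "ScreenResult",
    "expand_adducts",
    "match_mz",
    "fit_rti_model",
    "rt_filter",
    "screen",
]

# Adducts considered per ionization mode: protonation in positive mode;
# deprotonation and chloride attachment in negative mode.
POLARITY_ADDUCTS: Dict[str, Tuple[str, ...]] = {
    "positive": ("[M+H]+",),
    "negative": ("[M-H]-", "[M+Cl]-"),
}


@dataclass
class SuspectEntry:
    """One chemical from a suspect list."""

    name: str
    formula: Optional[MolecularFormula] = None
    exact_mass: Optional[float] = None
    rti: Optional[float] = None
    exposure_score: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.formula is None and self.exact_mass is None:
            raise ValueError(f"suspect {self.name!r}: needs a formula or an exact mass")
        if self.rti is not None and not np.isfinite(self.rti):
            raise ValueError(f"suspect {self.name!r}: non-finite RTI")

    @property
    def neutral_mass(self) -> float:
        if self.exact_mass is not None:
            return self.exact_mass
        return monoisotopic_mass(self.formula)  # type: ignore[arg-type]


@dataclass
class CandidateIon:
    suspect: SuspectEntry
    adduct: Adduct
    mz: float


@dataclass
class SuspectMatch:
    """A feature/suspect pairing within the mass tolerance."""

    feature_id: str
    feature_mz: float
    feature_rt: float
    suspect: SuspectEntry
    adduct: Adduct
    error_mda: float
    predicted_rt: Optional[float] = None
    rt_deviation: Optional[float] = None
    passed_rt_filter: Optional[bool] = None


def expand_adducts(
    suspects: Sequence[SuspectEntry], polarity: str
) -> List[CandidateIon]:
    """One candidate ion per suspect x applicable adduct for the mode."""
    if polarity not in POLARITY_ADDUCTS:
        raise ValueError(f"unknown polarity {polarity!r}")
    out: List[CandidateIon] = []
    for s in suspects:
        try:
            mass = s.neutral_mass
        except Exception:
            warnings.warn(f"suspect {s.name!r} skipped: no usable mass")
            continue
        for name in POLARITY_ADDUCTS[polarity]:
            adduct = ADDUCTS[name]
            out.append(CandidateIon(s, adduct, adduct_mz(mass, adduct)))
    return out


def match_mz(
    features: Sequence[Feature],
    candidates: Sequence[CandidateIon],
    tol_mda: float = 2.0,
) -> List[SuspectMatch]:
    """All feature/candidate pairs with |dm/z| <= ``tol_mda`` (inclusive).

    Multi-matching is allowed: one feature may match several suspects and
    vice versa; downstream RT filtering arbitrates.
    """
    # tiny epsilon keeps the boundary inclusive under binary rounding
    tol = tol_mda / 1000.0 + 1e-12
    if not features or not candidates:
        return []
    cand_mz = np.array([c.mz for c in candidates])
    order = np.argsort(cand_mz)
    sorted_mz = cand_mz[order]
    matches: List[SuspectMatch] = []
    for f in features:
        lo = np.searchsorted(sorted_mz, f.mz - tol, side="left")
        hi = np.searchsorted(sorted_mz, f.mz + tol, side="right")
        for idx in order[lo:hi]:
            c = candidates[idx]
            if abs(f.mz - c.mz) <= tol:
                matches.append(
                    SuspectMatch(
                        feature_id=f.id,
                        feature_mz=f.mz,
                        feature_rt=f.rt,
                        suspect=c.suspect,
                        adduct=c.adduct,
                        error_mda=(f.mz - c.mz) * 1e3,
                    )
                )
    return matches


@dataclass
class RtiModel:
    """Linear map RTI = slope * RT(s) + intercept fitted on calibrants."""

    slope: float
    intercept: float
    r_squared: float
    n_calibrants: int

    def predict_rt(self, rti: float) -> float:
        """Invert the calibration to predict RT (s) from a suspect's RTI."""
        if self.slope == 0:
            raise ValueError("RTI model slope is zero; cannot invert")
        return (rti - self.intercept) / self.slope


def fit_rti_model(calibrants: Sequence[Tuple[float, float]]) -> RtiModel:
    """Ordinary least squares of RTI on measured RT over (rt_s, rti) pairs."""
    if len(calibrants) < 2:
        raise ValueError("need at least 2 calibrants")
    rt = np.array([c[0] for c in calibrants], dtype=float)
    rti = np.array([c[1] for c in calibrants], dtype=float)
    if np.ptp(rt) == 0:
        raise ValueError("degenerate calibrants: all retention times equal")
    fit = stats.linregress(rt, rti)
    r2 = float(fit.rvalue) ** 2 if np.ptp(rti) > 0 else 1.0
    return RtiModel(float(fit.slope), float(fit.intercept), r2, len(calibrants))


def rt_filter(
    matches: Sequence[SuspectMatch],
    model: RtiModel,
    window_seconds: float = 120.0,
) -> List[SuspectMatch]:
    """Flag matches whose observed RT is within ``window_seconds``
    (inclusive) of the RT predicted from the suspect's RTI.

    Suspects without an RTI pass by default (flagged with an unset
    prediction) so list coverage gaps do not silently drop candidates.
    """
    out: List[SuspectMatch] = []
    for m in matches:
        if m.suspect.rti is None:
            warnings.warn(
                f"suspect {m.suspect.name!r} has no RTI; match passes RT filter unchecked"
            )
            out.append(
                SuspectMatch(
                    m.feature_id, m.feature_mz, m.feature_rt, m.suspect, m.adduct,
                    m.error_mda, None, None, True,
                )
            )
            continue
        predicted = model.predict_rt(m.suspect.rti)
        deviation = m.feature_rt - predicted
        out.append(
            SuspectMatch(
                m.feature_id, m.feature_mz, m.feature_rt, m.suspect, m.adduct,
                m.error_mda, predicted, deviation, abs(deviation) <= window_seconds,
            )
        )
    return out


@dataclass
class ScreenResult:
    """Per-list screening summary."""

    list_name: str
    matches: List[SuspectMatch] = field(default_factory=list)

    @property
    def n_features_matched(self) -> int:
        return len({m.feature_id for m in self.matches})

    @property
    def n_multi_matched(self) -> int:
        counts: Dict[str, set] = {}
        for m in self.matches:
            counts.setdefault(m.feature_id, set()).add(m.suspect.name)
        return sum(1 for names in counts.values() if len(names) > 1)

    @property
    def n_passing_rt(self) -> int:
        return len({m.feature_id for m in self.matches if m.passed_rt_filter})


def screen(
    features: Sequence[Feature],
    suspect_lists: Dict[str, Sequence[SuspectEntry]],
    calibrants: Sequence[Tuple[float, float]],
    tol_mda: float = 2.0,
    rt_window_seconds: float = 120.0,
) -> Dict[str, ScreenResult]:
    """Full suspect screen: expand adducts, match m/z, fit the RTI model on
    calibrants, and apply the RT plausibility filter, per suspect list."""
    model = fit_rti_model(calibrants)
    logger.info(
        "RTI model: slope=%.4g intercept=%.4g R^2=%.4f (n=%d)",
        model.slope, model.intercept, model.r_squared, model.n_calibrants,
    )
    results: Dict[str, ScreenResult] = {}
    by_polarity = {
        pol: [f for f in features if f.polarity == pol]
        for pol in ("positive", "negative")
    }
    for list_name, suspects in suspect_lists.items():
        all_matches: List[SuspectMatch] = []
        for pol, feats in by_polarity.items():
            if not feats:
                continue
            candidates = expand_adducts(suspects, pol)
            all_matches.extend(match_mz(feats, candidates, tol_mda))
        result = ScreenResult(list_name, rt_filter(all_matches, model, rt_window_seconds))
        logger.info(
            "list %s: %d features matched (%d multi-matched), %d pass RT filter",
            list_name, result.n_features_matched, result.n_multi_matched,
            result.n_passing_rt,
        )
        results[list_name] = result
    return results
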