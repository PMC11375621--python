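"""Semi-quantification and toxicity-weighted priority ranking.

Concentrations of unidentified features are estimated without reference
standards by transferring predicted electrospray ionization efficiencies
(log IE) to instrument-specific response factors: calibration chemicals
with known curves anchor a linear map log10(RF) ~ log IE, which then
converts any feature's predicted log IE into an RF and its integrated
area into a molar concentration. The priority score is a hazard
quotient, predicted concentration / predicted LC50 (both mM) — a
comparative ranking device, not an absolute risk estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .chem import MolecularFormula, monoisotopic_mass

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "ResponseFactor",
    "RejectedCurve",
    "IeTransferModel",
    "PriorityRecord",
    "ToxicityPredictor",
    "LookupToxicityPredictor",
    "ConstantToxicityPredictor",
    "fit_response_factor",
    "fit_ie_transfer",
    "predict_concentration",
    "priority_score",
    "rank_features",
]


@dataclass
class CalibrationCurve:
    """Dilution series for one chemical: (concentration ng/mL, area) pairs."""

    chemical: str
    formula: MolecularFormula
    levels: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.levels]
        if len(self.levels) < 2:
            raise ValueError(f"{self.chemical}: need at least 2 calibration levels")
        if any(c <= 0 for c in concs) or len(set(concs)) != len(concs):
            raise ValueError(f"{self.chemical}: concentrations must be positive and distinct")

    def levels_micromolar(self) -> List[Tuple[float, float]]:
        """Convert ng/mL to uM via the molecular mass (ng/mL == ug/L;
        ug/L divided by g/mol gives umol/L)."""
        mw = monoisotopic_mass(self.formula)
        return [(c / mw, a) for c, a in self.levels]


@dataclass
class ResponseFactor:
    """Instrument response per unit concentration (area per uM)."""

    chemical: str
    rf: float
    n_levels_used: int

    def __post_init__(self) -> None:
        if self.rf <= 0:
            raise ValueError(f"{self.chemical}: response factor must be positive")


@dataclass
class RejectedCurve:
    chemical: str
    reason: str


def fit_response_factor(
    curve: CalibrationCurve, min_levels: int = 5
) -> ResponseFactor | RejectedCurve:
    """Least-squares slope of area on concentration (uM) through the origin.

    Curves detected at fewer than ``min_levels`` levels are rejected, as is
    a non-positive fitted slope.
    """
    levels = curve.levels_micromolar()
    if len(levels) < min_levels:
        return RejectedCurve(
            curve.chemical, f"only {len(levels)} levels detected (< {min_levels})"
        )
    x = np.array([c for c, _ in levels])
    y = np.array([a for _, a in levels])
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        return RejectedCurve(curve.chemical, f"non-positive response slope {slope:.3g}")
    return ResponseFactor(curve.chemical, slope, len(levels))


@dataclass
class IeTransferModel:
    """Linear map log10(RF) = slope * logIE + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_calibrants: int

    def response_factor(self, log_ie: float) -> float:
        return float(10.0 ** (self.slope * log_ie + self.intercept))


def fit_ie_transfer(
    calibrant_rfs: Sequence[ResponseFactor],
    predicted_log_ie: Dict[str, float],
) -> IeTransferModel:
    """OLS of log10(measured RF) on predicted log IE over the calibrants."""
    pairs = [
        (predicted_log_ie[rf.chemical], np.log10(rf.rf))
        for rf in calibrant_rfs
        if rf.chemical in predicted_log_ie
    ]
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibrants with predicted log IE")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all log IE values equal")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue) ** 2 if np.ptp(y) > 0 else 1.0
    logger.info(
        "IE-transfer model: slope=%.4f intercept=%.4f R^2=%.4f (n=%d)",
        fit.slope, fit.intercept, r2, len(pairs),
    )
    return IeTransferModel(float(fit.slope), float(fit.intercept), r2, len(pairs))


def predict_concentration(
    area: float, log_ie_pred: float, transfer: IeTransferModel
) -> float:
    """Concentration in mM from an integrated area and a predicted log IE."""
    if area < 0:
        raise ValueError("area must be non-negative")
    rf = transfer.response_factor(log_ie_pred)
    conc_um = area / rf
    return conc_um / 1000.0


def priority_score(concentration_mm: float, lc50_mm: float) -> float:
    """Hazard quotient: predicted concentration / predicted LC50 (both mM)."""
    if lc50_mm <= 0:
        raise ValueError(f"LC50 must be positive, got {lc50_mm}")
    return concentration_mm / lc50_mm


# Pluggable toxicity predictor: structure id -> predicted LC50 (mM).
ToxicityPredictor = Callable[[str], Optional[float]]


@dataclass
class LookupToxicityPredictor:
    """Table-backed predictor for chemicals with known or precomputed LC50."""

    table: Dict[str, float]

    def __call__(self, structure_id: str) -> Optional[float]:
        return self.table.get(structure_id)


@dataclass
class ConstantToxicityPredictor:
    """Baseline predictor returning one LC50 for every structure (mM)."""

    lc50_mm: float = 1.0

    def __call__(self, structure_id: str) -> Optional[float]:
        return self.lc50_mm


@dataclass
class PriorityRecord:
    """A feature with its predicted concentration, toxicity and score.

    ``predicted_concentration`` may be None (e.g. negative-mode features
    where quantification is unavailable); such records are ranked by
    toxicity alone.
    """

    feature_id: str
    predicted_concentration: Optional[float]  # mM
    predicted_lc50: float  # mM
    priority_score: Optional[float] = field(default=None)
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.predicted_lc50 <= 0:
            raise ValueError(f"{self.feature_id}: LC50 must be positive")
        if self.predicted_concentration is not None and self.priority_score is None:
            self.priority_score = priority_score(
                self.predicted_concentration, self.predicted_lc50
            )


def rank_features(records: Sequence[PriorityRecord]) -> List[PriorityRecord]:
    """Assign ranks by descending priority score; ties break toward lower
    LC50 (more toxic first), then feature id. Records without a score
    (no concentration) sort after scored ones, by ascending LC50."""

    def key(r: PriorityRecord):
        scored = r.priority_score is not None
        return (
            0 if scored else 1,
            -(r.priority_score or 0.0),
            r.predicted_lc50,
            r.feature_id,
        )

    ordered = sorted(records, key=key)
    out = []
    for i, r in enumerate(ordered, start=1):
        out.append(
            PriorityRecord(
                r.feature_id,
                r.predicted_concentration,
                r.predicted_lc50,
                r.priority_score,
                rank=i,
            )
        )
    return out
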