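"""Consensus structural annotation with confidence levels.

Three evidence streams are combined per feature: spectral-library matches
(greedy matched-peak cosine similarity), forward and inverse in-silico
fragmentation candidates from external engines (consumed as candidate
tables, never recomputed here), and bare formula assignments. Agreement
between the two in-silico engines is tested with Tanimoto similarity of
their candidates' molecular fingerprints. The chosen structure is assigned
a confidence level on the Schymanski scale: 2b for an online library
match, 3 for a concordant in-silico structure, 4 for an unequivocal
formula, 5 for an unknown. Level 1 (confirmed by reference standard)
requires a local standard library and is never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .features import MS2Spectrum

__all__ = [
    "LibrarySpectrum",
    "AnnotationCandidate",
    "ConsensusAnnotation",
    "ConsensusConfig",
    "cosine_score",
    "matched_peak_pairs",
    "library_match",
    "tanimoto",
    "consensus_annotate",
]

CANDIDATE_SOURCES = ("library", "silico_forward", "silico_inverse", "formula_only")


@dataclass
class LibrarySpectrum:
    """A reference spectrum with its structure identity."""

    structure_id: str
    spectrum: MS2Spectrum
    name: str = ""
    formula: str = ""

    def __post_init__(self) -> None:
        self.spectrum = self.spectrum.normalized()


def matched_peak_pairs(
    a: MS2Spectrum, b: MS2Spectrum, frag_tol_mda: float = 5.0
) -> List[Tuple[int, int]]:
    """Greedy one-to-one fragment pairing within tolerance.

    Candidate pairs are ranked by intensity product (descending) and
    assigned greedily so each peak is used at most once.
    """
    tol = frag_tol_mda / 1000.0
    pairs = [
        (a.peaks[i][1] * b.peaks[j][1], i, j)
        for i in range(len(a.peaks))
        for j in range(len(b.peaks))
        if abs(a.peaks[i][0] - b.peaks[j][0]) <= tol
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set = set()
    used_b: set = set()
    out: List[Tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    return out


def cosine_score(
    a: MS2Spectrum, b: MS2Spectrum, frag_tol_mda: float = 5.0
) -> float:
    """Cosine similarity over greedily matched fragment pairs.

    Unmatched peaks contribute to the norms but not the dot product, so
    the score is 1 only for identical spectra and 0 for disjoint ones.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("cannot score an empty spectrum")
    pairs = matched_peak_pairs(a, b, frag_tol_mda)
    dot = sum(a.peaks[i][1] * b.peaks[j][1] for i, j in pairs)
    norm = np.sqrt(
        sum(i**2 for _, i in a.peaks) * sum(i**2 for _, i in b.peaks)
    )
    return float(dot / norm)


@dataclass
class AnnotationCandidate:
    """One candidate structure (or formula) for a feature, from one engine.

    ``score`` is on the engine's native scale and is comparable only within
    a source; for library candidates it is the cosine similarity.
    """

    structure_id: str
    source: str
    score: float
    matched_peaks: int = 0
    fingerprint: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.source not in CANDIDATE_SOURCES:
            raise ValueError(f"unknown candidate source {self.source!r}")
        if self.matched_peaks < 0:
            raise ValueError("matched_peaks must be non-negative")
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=bool)


def library_match(
    spectrum: MS2Spectrum,
    library: Sequence[LibrarySpectrum],
    min_cosine: float = 0.5,
    frag_tol_mda: float = 5.0,
) -> List[AnnotationCandidate]:
    """Rank library entries scoring strictly above ``min_cosine``.

    Ties are broken by matched-peak count (descending), then structure id.
    """
    scored = []
    for entry in library:
        score = cosine_score(spectrum, entry.spectrum, frag_tol_mda)
        if score > min_cosine:
            n_matched = len(matched_peak_pairs(spectrum, entry.spectrum, frag_tol_mda))
            scored.append(
                AnnotationCandidate(entry.structure_id, "library", score, n_matched)
            )
    scored.sort(key=lambda c: (-c.score, -c.matched_peaks, c.structure_id))
    return scored


def tanimoto(fp_a: Union[np.ndarray, str], fp_b: Union[np.ndarray, str]) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length fingerprint
    bitvectors; defined as 1 when both are all-zero."""
    a = _as_bits(fp_a)
    b = _as_bits(fp_b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b)) / union


def _as_bits(fp: Union[np.ndarray, str]) -> np.ndarray:
    if isinstance(fp, str):
        return np.array([c == "1" for c in fp], dtype=bool)
    return np.asarray(fp, dtype=bool)


@dataclass
class ConsensusConfig:
    min_cosine: float = 0.5
    min_matched_peaks: int = 3  # "> 2 MS2 peaks"
    min_tanimoto: float = 0.8


@dataclass
class ConsensusAnnotation:
    """The chosen structure (or formula) and its confidence level.

    ``confidence`` is one of "2b", "3", "4", "5"; ``evidence`` records
    which decision clauses fired and why.
    """

    feature_id: str
    structure_id: Optional[str]
    confidence: str
    evidence: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.confidence not in ("2b", "3", "4", "5"):
            raise ValueError(f"invalid confidence level {self.confidence!r}")


def _top(candidates: List[AnnotationCandidate]) -> Optional[AnnotationCandidate]:
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-c.score, -c.matched_peaks, c.structure_id))


def consensus_annotate(
    feature_id: str,
    candidates: Sequence[AnnotationCandidate],
    config: Optional[ConsensusConfig] = None,
) -> ConsensusAnnotation:
    """Combine per-engine candidates into one annotation with a level.

    Decision clauses, in order:

    a. best library candidate with cosine above the threshold and enough
       matched peaks -> its structure, Level 2b;
    b. else, if the forward and inverse in-silico top candidates each match
       enough peaks and their fingerprints agree (Tanimoto above
       threshold) -> the better-supported engine's structure, Level 3;
    c. else, if the formula candidates agree on a single formula -> that
       formula, Level 4;
    d. else Level 5 (unknown).
    """
    cfg = config or ConsensusConfig()
    by_source: Dict[str, List[AnnotationCandidate]] = {s: [] for s in CANDIDATE_SOURCES}
    for c in candidates:
        by_source[c.source].append(c)
    evidence: List[str] = []

    lib = _top(
        [
            c
            for c in by_source["library"]
            if c.score > cfg.min_cosine and c.matched_peaks >= cfg.min_matched_peaks
        ]
    )
    if lib is not None:
        evidence.append(
            f"library match {lib.structure_id} cosine={lib.score:.3f} "
            f"matched_peaks={lib.matched_peaks} -> Level 2b"
        )
        return ConsensusAnnotation(feature_id, lib.structure_id, "2b", evidence)
    if by_source["library"]:
        evidence.append("library candidates present but below cosine/peak thresholds")

    fwd = _top(by_source["silico_forward"])
    inv = _top(by_source["silico_inverse"])
    if fwd is not None and inv is not None:
        if (
            fwd.matched_peaks >= cfg.min_matched_peaks
            and inv.matched_peaks >= cfg.min_matched_peaks
            and fwd.fingerprint is not None
            and inv.fingerprint is not None
        ):
            sim = tanimoto(fwd.fingerprint, inv.fingerprint)
            if sim > cfg.min_tanimoto:
                chosen = max((fwd, inv), key=lambda c: (c.matched_peaks, c is fwd))
                evidence.append(
                    f"in-silico agreement tanimoto={sim:.3f} "
                    f"(forward {fwd.structure_id}, inverse {inv.structure_id}) "
                    f"-> {chosen.structure_id} Level 3"
                )
                return ConsensusAnnotation(feature_id, chosen.structure_id, "3", evidence)
            evidence.append(f"in-silico tops disagree (tanimoto={sim:.3f})")
        else:
            evidence.append("in-silico candidates lack matched peaks or fingerprints")

    formulas = {c.structure_id for c in by_source["formula_only"]}
    if len(formulas) == 1:
        formula = formulas.pop()
        evidence.append(f"unequivocal formula {formula} -> Level 4")
        return ConsensusAnnotation(feature_id, formula, "4", evidence)
    if formulas:
        evidence.append(f"ambiguous formulas ({len(formulas)} distinct)")

    evidence.append("no supported annotation -> Level 5")
    return ConsensusAnnotation(feature_id, None, "5", evidence)
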