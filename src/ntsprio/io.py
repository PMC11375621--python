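"""Readers and writers for the workflow's on-disk formats.

Feature tables, experiment designs, suspect lists, calibration series and
candidate tables travel as UTF-8 comma-separated CSV with a mandatory
header and "." decimals. Fragment spectra are read and written as MGF
(via pyteomics) and spectral libraries as MSP. Retention-time columns may
be named ``rt`` / ``rt_s`` (seconds) or ``rt_min`` (minutes, converted on
load).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as pyteomics_mgf

from .annotation import AnnotationCandidate, ConsensusAnnotation, LibrarySpectrum
from .chem import parse_formula
from .features import ExperimentDesign, Feature, FilterTrace, MS2Spectrum
from .prioritize import CalibrationCurve, PriorityRecord
from .suspects import ScreenResult, SuspectEntry

__all__ = [
    "SchemaError",
    "read_design", "write_design",
    "read_feature_table", "write_feature_table",
    "read_mgf", "write_mgf",
    "read_msp", "write_msp",
    "read_suspects", "write_suspects",
    "read_calibration", "write_calibration",
    "read_candidates", "write_candidates",
    "write_annotations", "write_matches", "write_priorities", "write_trace",
    "write_bundle",
]

PathLike = Union[str, os.PathLike]


class SchemaError(ValueError):
    """A file is readable but its columns/headers do not match the schema."""


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path: PathLike) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _rt_seconds(df: pd.DataFrame, path: PathLike) -> pd.Series:
    if "rt" in df.columns or "rt_s" in df.columns:
        return df["rt"] if "rt" in df.columns else df["rt_s"]
    if "rt_min" in df.columns:
        return df["rt_min"] * 60.0
    raise SchemaError(f"{path}: need an rt / rt_s / rt_min column")


# --- design ---------------------------------------------------------------

def read_design(path: PathLike) -> ExperimentDesign:
    df = pd.read_csv(path)
    _require_columns(df, ["replicate_id", "sample_id", "is_blank"], path)
    samples: Dict[str, List[str]] = {}
    blanks: List[str] = []
    for _, row in df.iterrows():
        if bool(row["is_blank"]):
            blanks.append(str(row["replicate_id"]))
        else:
            samples.setdefault(str(row["sample_id"]), []).append(str(row["replicate_id"]))
    return ExperimentDesign(samples=samples, blanks=blanks)


def write_design(design: ExperimentDesign, path: PathLike) -> None:
    rows = [
        {"replicate_id": rep, "sample_id": sample, "is_blank": False}
        for sample, reps in design.samples.items()
        for rep in reps
    ]
    rows += [{"replicate_id": b, "sample_id": "blank", "is_blank": True} for b in design.blanks]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- feature tables -------------------------------------------------------

def read_feature_table(path: PathLike, design: ExperimentDesign) -> List[Feature]:
    df = pd.read_csv(path)
    _require_columns(df, ["feature_id", "mz", "polarity"], path)
    rt = _rt_seconds(df, path)
    rep_cols = [c for c in df.columns if c in set(design.replicate_ids)]
    if not rep_cols:
        raise SchemaError(f"{path}: no replicate intensity columns match the design")
    features = []
    for i, row in df.iterrows():
        intensities = {
            rep: float(row[rep]) for rep in rep_cols if pd.notna(row[rep]) and row[rep] > 0
        }
        features.append(
            Feature(
                id=str(row["feature_id"]), mz=float(row["mz"]), rt=float(rt.iloc[i]),
                polarity=str(row["polarity"]), intensities=intensities,
            )
        )
    return features


def write_feature_table(
    features: Sequence[Feature], design: ExperimentDesign, path: PathLike
) -> None:
    reps = design.replicate_ids
    rows = []
    for f in features:
        row: Dict[str, object] = {
            "feature_id": f.id, "mz": f.mz, "rt_s": f.rt, "polarity": f.polarity,
        }
        for rep in reps:
            row[rep] = f.intensities.get(rep, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=["feature_id", "mz", "rt_s", "polarity"] + reps).to_csv(
        path, index=False
    )


# --- MGF / MSP ------------------------------------------------------------

def read_mgf(path: PathLike) -> List[Tuple[str, MS2Spectrum]]:
    """Read (title, spectrum) pairs from an MGF file."""
    out = []
    with pyteomics_mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise SchemaError(f"{path}: MGF block without PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            rt = float(params.get("rtinseconds", 0.0))
            energy = params.get("collision_energy")
            peaks = list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            out.append(
                (
                    str(params.get("title", "")),
                    MS2Spectrum(precursor, rt, float(energy) if energy is not None else None, peaks),
                )
            )
    return out


def write_mgf(spectra: Sequence[Tuple[str, MS2Spectrum]], path: PathLike) -> None:
    entries = []
    for title, s in spectra:
        params = {"title": title, "pepmass": s.precursor_mz, "rtinseconds": s.rt}
        if s.collision_energy is not None:
            params["collision_energy"] = s.collision_energy
        entries.append(
            {
                "params": params,
                "m/z array": np.array([m for m, _ in s.peaks]),
                "intensity array": np.array([i for _, i in s.peaks]),
            }
        )
    pyteomics_mgf.write(entries, str(path), file_mode="w")


def read_msp(path: PathLike) -> List[LibrarySpectrum]:
    """Minimal MSP reader: Name / PrecursorMZ / RetentionTime / Formula
    headers plus "Num Peaks" and m/z-intensity lines."""
    entries: List[LibrarySpectrum] = []
    meta: Dict[str, str] = {}
    peaks: List[Tuple[float, float]] = []

    def flush() -> None:
        if not meta:
            return
        if "name" not in meta:
            raise SchemaError(f"{path}: MSP block without Name")
        if not peaks:
            raise SchemaError(f"{path}: MSP block {meta.get('name')!r} without peaks")
        spectrum = MS2Spectrum(
            float(meta.get("precursormz", 0.0)),
            float(meta.get("retentiontime", 0.0)),
            None,
            list(peaks),
        )
        entries.append(
            LibrarySpectrum(
                structure_id=meta["name"], spectrum=spectrum,
                name=meta["name"], formula=meta.get("formula", ""),
            )
        )

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                meta, peaks = {}, []
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                meta[key.strip().lower().replace(" ", "")] = value.strip()
            else:
                parts = line.replace("\t", " ").split()
                peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return entries


def write_msp(entries: Sequence[LibrarySpectrum], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"Name: {e.structure_id}\n")
            if e.formula:
                fh.write(f"Formula: {e.formula}\n")
            fh.write(f"PrecursorMZ: {e.spectrum.precursor_mz}\n")
            fh.write(f"RetentionTime: {e.spectrum.rt}\n")
            fh.write(f"Num Peaks: {len(e.spectrum.peaks)}\n")
            for m, i in e.spectrum.peaks:
                fh.write(f"{m} {i}\n")
            fh.write("\n")


# --- suspect lists --------------------------------------------------------

def read_suspects(path: PathLike) -> List[SuspectEntry]:
    df = pd.read_csv(path)
    _require_columns(df, ["Name"], path)
    if "Formula" not in df.columns and "MonoisotopicMass" not in df.columns:
        raise SchemaError(f"{path}: need a Formula and/or MonoisotopicMass column")
    out = []
    for _, row in df.iterrows():
        formula = None
        if "Formula" in df.columns and isinstance(row.get("Formula"), str) and row["Formula"]:
            formula = parse_formula(row["Formula"])
        mass = None
        if "MonoisotopicMass" in df.columns and pd.notna(row.get("MonoisotopicMass")):
            mass = float(row["MonoisotopicMass"])
        rti = float(row["RTI"]) if "RTI" in df.columns and pd.notna(row.get("RTI")) else None
        score = (
            int(row["ExposureScore"])
            if "ExposureScore" in df.columns and pd.notna(row.get("ExposureScore"))
            else None
        )
        out.append(
            SuspectEntry(
                name=str(row["Name"]), formula=formula, exact_mass=mass, rti=rti,
                exposure_score=score, source=str(row.get("Source", "")),
            )
        )
    return out


def write_suspects(suspects: Sequence[SuspectEntry], path: PathLike) -> None:
    rows = []
    for s in suspects:
        rows.append(
            {
                "Name": s.name,
                "Formula": s.formula.hill() if s.formula else "",
                "MonoisotopicMass": s.exact_mass if s.exact_mass is not None else "",
                "RTI": s.rti if s.rti is not None else "",
                "ExposureScore": s.exposure_score if s.exposure_score is not None else "",
                "Source": s.source,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# --- calibration ----------------------------------------------------------

def read_calibration(path: PathLike) -> List[CalibrationCurve]:
    df = pd.read_csv(path)
    _require_columns(df, ["chemical", "formula", "level_ng_per_ml", "area"], path)
    curves = []
    for (chemical, formula), grp in df.groupby(["chemical", "formula"], sort=False):
        levels = list(zip(grp["level_ng_per_ml"].astype(float), grp["area"].astype(float)))
        curves.append(CalibrationCurve(str(chemical), parse_formula(str(formula)), levels))
    return curves


def write_calibration(curves: Sequence[CalibrationCurve], path: PathLike) -> None:
    rows = [
        {
            "chemical": c.chemical, "formula": c.formula.hill(),
            "level_ng_per_ml": conc, "area": area,
        }
        for c in curves
        for conc, area in c.levels
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- candidate tables -----------------------------------------------------

def _fingerprint_to_str(fp: Optional[np.ndarray]) -> str:
    if fp is None:
        return ""
    return "".join("1" if b else "0" for b in fp)


def read_candidates(path: PathLike) -> Dict[str, List[AnnotationCandidate]]:
    df = pd.read_csv(path, dtype={"fingerprint": str})
    _require_columns(df, ["feature_id", "source", "structure_id", "score"], path)
    out: Dict[str, List[AnnotationCandidate]] = {}
    for _, row in df.iterrows():
        fp = None
        if "fingerprint" in df.columns and isinstance(row.get("fingerprint"), str) and row["fingerprint"]:
            fp = np.array([c == "1" for c in row["fingerprint"]], dtype=bool)
        out.setdefault(str(row["feature_id"]), []).append(
            AnnotationCandidate(
                structure_id=str(row["structure_id"]), source=str(row["source"]),
                score=float(row["score"]),
                matched_peaks=int(row["matched_peaks"]) if "matched_peaks" in df.columns and pd.notna(row.get("matched_peaks")) else 0,
                fingerprint=fp,
            )
        )
    return out


def write_candidates(
    candidates: Dict[str, Sequence[AnnotationCandidate]], path: PathLike
) -> None:
    rows = [
        {
            "feature_id": fid, "source": c.source, "structure_id": c.structure_id,
            "score": c.score, "matched_peaks": c.matched_peaks,
            "fingerprint": _fingerprint_to_str(c.fingerprint),
        }
        for fid, cands in candidates.items()
        for c in cands
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- outputs --------------------------------------------------------------

def write_annotations(annotations: Sequence[ConsensusAnnotation], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": a.feature_id,
                "structure_id": a.structure_id if a.structure_id else "",
                "confidence": a.confidence,
                "evidence": "; ".join(a.evidence),
            }
            for a in annotations
        ]
    ).to_csv(path, index=False)


def write_matches(results: Dict[str, ScreenResult], path: PathLike) -> None:
    rows = []
    for list_name, result in results.items():
        for m in result.matches:
            rows.append(
                {
                    "list": list_name,
                    "feature_id": m.feature_id,
                    "suspect": m.suspect.name,
                    "formula": m.suspect.formula.hill() if m.suspect.formula else "",
                    "exact_mass": m.suspect.neutral_mass,
                    "feature_mz": m.feature_mz,
                    "rt_min": m.feature_rt / 60.0,
                    "adduct": m.adduct.name,
                    "error_mda": m.error_mda,
                    "predicted_rt_s": m.predicted_rt if m.predicted_rt is not None else "",
                    "passed_rt_filter": m.passed_rt_filter,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_priorities(records: Sequence[PriorityRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "rank": r.rank,
                "feature_id": r.feature_id,
                "predicted_concentration_mM": (
                    r.predicted_concentration if r.predicted_concentration is not None else ""
                ),
                "predicted_LC50_mM": r.predicted_lc50,
                "priority_score": r.priority_score if r.priority_score is not None else "",
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_trace(trace: FilterTrace, path: PathLike) -> None:
    pd.DataFrame(trace.as_rows()).to_csv(path, index=False)


# --- bundle export --------------------------------------------------------

def write_bundle(bundle, out_dir: PathLike) -> None:
    """Write a synthetic TruthBundle as the pipeline's input formats plus
    truth labels (truth.csv, rti_calibrants.csv, eics.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_design(bundle.design, out / "design.csv")
    write_feature_table(bundle.features, bundle.design, out / "features.csv")
    write_mgf(
        [(f"spec_{i}", s) for i, s in enumerate(bundle.spectra)], out / "spectra.mgf"
    )
    write_msp(bundle.library, out / "library.msp")
    write_suspects(bundle.suspects, out / "suspects.csv")
    write_calibration(bundle.calibration.curves, out / "calibration.csv")
    write_candidates(bundle.candidates, out / "candidates.csv")
    pd.DataFrame(
        {"rt_s": [c[0] for c in bundle.rti_calibrants],
         "rti": [c[1] for c in bundle.rti_calibrants]}
    ).to_csv(out / "rti_calibrants.csv", index=False)
    pd.DataFrame(
        [
            {"chemical": name, "log_ie": bundle.calibration.log_ie[name]}
            for name in bundle.calibration.log_ie
        ]
    ).to_csv(out / "log_ie.csv", index=False)
    bundle.truth.to_csv(out / "truth.csv", index=False)
    eic_rows = [
        {"feature_id": fid, "index": i, "intensity": v}
        for fid, trace in bundle.eics.items()
        for i, v in enumerate(np.asarray(trace))
    ]
    pd.DataFrame(eic_rows).to_csv(out / "eics.csv", index=False)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({k: _plain(v) for k, v in vars(bundle.config).items()}, fh)


def _plain(value):
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value
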