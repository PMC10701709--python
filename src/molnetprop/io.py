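"""Readers and writers for feature tables, MGF spectra, seeds and results.

Feature ids are opaque strings and authoritative: tables are joined on
ids only, never on m/z-RT proximity.  Retention time is stored in
seconds internally; readers convert from minutes when told to.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .formula import MolecularFormula, parse_formula

__all__ = [
    "Feature",
    "Spectrum",
    "SeedAnnotation",
    "FeatureTableError",
    "MgfError",
    "read_feature_table",
    "read_mgf",
    "write_mgf",
    "read_seed_table",
    "write_annotation_table",
    "write_level_summary",
    "match_spectra_to_features",
    "split_by_polarity",
]

log = logging.getLogger(__name__)


class FeatureTableError(ValueError):
    """Structural problem in a feature or seed table (carries row context)."""


class MgfError(ValueError):
    """Unparseable MGF block."""


@dataclass(frozen=True)
class Feature:
    """One aligned LC-MS feature: the node unit of every network."""

    id: str
    mz: float
    rt: float  # seconds
    intensity: float = 0.0
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.id}: m/z must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.id}: RT must be non-negative")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"feature {self.id}: polarity {self.polarity!r}")


@dataclass(frozen=True)
class Spectrum:
    """An MS2 spectrum keyed to a feature; peaks sorted by m/z."""

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.size == 0:
            raise ValueError(f"spectrum {self.feature_id}: needs at least one peak")
        if mz.size != inten.size:
            raise ValueError(f"spectrum {self.feature_id}: mz/intensity length mismatch")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensities", inten[order])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class SeedAnnotation:
    """A manually annotated feature: the unit of the seed node set."""

    feature_id: str
    name: str
    formula: MolecularFormula | None = None
    compound_class: str = ""


_DEFAULT_COLUMNS = {
    "id": "id",
    "mz": "mz",
    "rt": "rt",
    "intensity": "intensity",
    "polarity": "polarity",
}


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_feature_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    rt_unit: str = "s",
    default_polarity: str = "negative",
) -> list[Feature]:
    """Read a feature table (CSV or TSV) into a list of :class:`Feature`.

    ``columns`` maps the internal field names (id, mz, rt, intensity,
    polarity) to the file's column headers.  ``rt_unit`` is ``"s"`` or
    ``"min"``; minutes are converted to seconds on read.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if rt_unit not in ("s", "min"):
        raise ValueError(f"rt_unit must be 's' or 'min', got {rt_unit!r}")
    df = _read_table(path)
    for key in ("id", "mz", "rt"):
        if colmap[key] not in df.columns:
            raise FeatureTableError(
                f"{path}: missing required column {colmap[key]!r} (for {key})"
            )
    features: list[Feature] = []
    seen: set[str] = set()
    scale = 60.0 if rt_unit == "min" else 1.0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        fid = str(rec[colmap["id"]]).strip()
        if fid in seen:
            raise FeatureTableError(f"{path} row {i}: duplicate feature id {fid!r}")
        seen.add(fid)
        try:
            mz = float(rec[colmap["mz"]])
            rt = float(rec[colmap["rt"]]) * scale
        except ValueError as exc:
            raise FeatureTableError(f"{path} row {i}: non-numeric m/z or RT") from exc
        inten = 0.0
        if colmap["intensity"] in rec and rec[colmap["intensity"]] != "":
            inten = float(rec[colmap["intensity"]])
        pol = default_polarity
        if colmap["polarity"] in rec and rec[colmap["polarity"]] != "":
            pol = str(rec[colmap["polarity"]]).strip().lower()
        features.append(Feature(fid, mz, rt, inten, pol))
    return features


def split_by_polarity(features: Iterable[Feature]) -> dict[str, list[Feature]]:
    """Split mixed-polarity input into per-polarity runs (networks are
    built per ionization mode)."""
    out: dict[str, list[Feature]] = {}
    for f in features:
        out.setdefault(f.polarity, []).append(f)
    return out


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read MS2 spectra from a Mascot generic format file.

    Each BEGIN IONS block must carry a feature id (``FEATURE_ID`` or,
    failing that, ``TITLE``) and ``PEPMASS``.  Peaks are returned sorted
    ascending; peakless blocks are skipped with a warning.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, block in enumerate(reader):
            params = block.get("params", {})
            fid = params.get("feature_id") or params.get("title")
            if fid is None:
                raise MgfError(f"{path}: block {i} has no FEATURE_ID or TITLE")
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MgfError(f"{path}: block {i} ({fid}) has no PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
            mz = np.asarray(block["m/z array"], dtype=float)
            if mz.size == 0:
                warnings.warn(f"{path}: block {i} ({fid}) has no peaks; skipped")
                continue
            spectra.append(
                Spectrum(str(fid), precursor, mz, np.asarray(block["intensity array"]))
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensities,
            "params": {"feature_id": s.feature_id, "pepmass": s.precursor_mz,
                       "title": s.feature_id},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def match_spectra_to_features(
    spectra: Iterable[Spectrum], features: Iterable[Feature]
) -> list[Spectrum]:
    """Keep spectra whose feature_id resolves to a feature; report orphans."""
    ids = {f.id for f in features}
    kept, orphans = [], []
    for s in spectra:
        (kept if s.feature_id in ids else orphans).append(s.feature_id)
    if orphans:
        log.warning("dropping %d spectra with no matching feature: %s",
                    len(orphans), orphans[:10])
    return [s for s in spectra if s.feature_id in ids]


def read_seed_table(
    path: str | Path, features: Sequence[Feature] | None = None
) -> list[SeedAnnotation]:
    """Read seed annotations (columns: feature_id, name, formula, class)."""
    df = _read_table(path)
    for col in ("feature_id", "name"):
        if col not in df.columns:
            raise FeatureTableError(f"{path}: missing required column {col!r}")
    known = {f.id for f in features} if features is not None else None
    seeds = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        fid = str(rec["feature_id"]).strip()
        if known is not None and fid not in known:
            raise FeatureTableError(
                f"{path} row {i}: seed feature id {fid!r} not in feature table"
            )
        formula = None
        if rec.get("formula"):
            formula = parse_formula(str(rec["formula"]))
        seeds.append(
            SeedAnnotation(fid, str(rec["name"]), formula,
                           str(rec.get("class", "") or ""))
        )
    return seeds


_ANNOTATION_COLUMNS = [
    "feature_id", "name", "formula", "seed_id", "level", "hop",
    "cosine", "transformation", "delta_mass", "series_id", "conflict",
]


def write_annotation_table(annotations: Iterable, path: str | Path) -> None:
    """Write propagated annotations to CSV (one row per surviving
    annotation; conflicting formulas on one feature appear as multiple
    rows sharing the feature id with the conflict flag set)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "feature_id": a.feature_id,
                "name": a.name,
                "formula": str(a.formula) if a.formula else "",
                "seed_id": a.seed_id,
                "level": "+".join(sorted(a.level)),
                "hop": a.hop,
                "cosine": "" if a.cosine is None else f"{a.cosine:.4f}",
                "transformation": a.transformation or "",
                "delta_mass": "" if a.delta_mass is None else f"{a.delta_mass:.6f}",
                "series_id": "" if a.series_id is None else a.series_id,
                "conflict": bool(a.conflict),
            }
        )
    df = pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS)
    df.sort_values(["feature_id", "formula", "seed_id"], inplace=True)
    df.to_csv(path, index=False)


def write_level_summary(summary: Mapping[str, int], path: str | Path) -> None:
    pd.Series(dict(summary), name="count").rename_axis("level").to_csv(path)
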