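"""Ground-truthed synthetic LC-MS/MS datasets.

The generator emulates the structure of a lipid-like compound class
measured in negative mode: a homologous series of glycerophospho
N-acyl ethanolamide (GPNAE)-like species differing by CH2 with a
linear retention-time trend, hexose (+162.0528 u) glyco-variants whose
fragmentation shifts intensity from the shared backbone fragments
toward internal glucose fragments (so the plain cosine to the aglycone
falls below the 0.8 network threshold while the precursor mass
difference still links them), isomeric decoys (same m/z, distant RT,
unrelated fragmentation — the lysophosphatidylethanolamine confusion),
partial MS2 coverage, and unrelated noise features.  Everything is
seeded and the ground truth records the identity of every feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formula import (
    MolecularFormula,
    Transformation,
    ion_mz,
    parse_formula,
)
from .io import Feature, SeedAnnotation, Spectrum

__all__ = ["FixtureSpec", "TruthRecord", "GroundTruth", "generate", "evaluate",
           "EvaluationReport"]

_H = parse_formula("H")
_HEXOSE = parse_formula("C6H10O5")
_CH2 = parse_formula("CH2")

#: backbone fragment ions shared by all members (m/z, relative intensity)
_BACKBONE_FRAGMENTS = [(79.9669, 100.0), (152.9958, 35.0), (171.0064, 90.0)]
#: internal glucose fragments characteristic of the glyco-variants
_GLUCOSE_FRAGMENTS = [(59.0133, 70.0), (89.0239, 60.0), (101.0244, 80.0),
                      (119.0708, 50.0)]
#: decoy (LPE-like) fragments: head-group ions unrelated to the backbone set
_DECOY_FRAGMENTS = [(78.9591, 90.0), (140.0118, 80.0), (196.0380, 55.0)]
#: neutral losses applied to the precursor (loss mass, relative intensity)
_NEUTRAL_LOSSES = [(74.0367, 55.0), (18.0106, 15.0), (97.9769, 25.0)]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic dataset.

    Defaults model a six-member GPNAE-like CH2 series eluting on a
    reversed-phase gradient (RT = 300 s + 30 s per CH2, 2 s jitter),
    half of the members carrying a hexose variant, three isomeric
    decoys, full MS2 coverage, ten noise singletons and 2 ppm mass
    error.
    """

    n_chain_lengths: int = 6
    base_formula: MolecularFormula = field(
        default_factory=lambda: parse_formula("C18H38NO7P")
    )
    base_name: str = "GPNAE 13:0"
    base_chain: int = 13
    unit: Transformation = field(
        default_factory=lambda: Transformation("Methylene", _CH2)
    )
    rt_intercept: float = 300.0
    rt_slope: float = 30.0
    rt_jitter: float = 2.0
    glyco_fraction: float = 0.5
    glyco_rt_offset: float = -150.0
    decoy_isomers: int = 3
    ms2_coverage: float = 1.0
    noise_features: int = 10
    mz_noise_ppm: float = 2.0
    charge: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chain_lengths < 4:
            raise ValueError("need at least 4 chain lengths for a series")
        for p in (self.glyco_fraction, self.ms2_coverage):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not self.base_formula.contains(_H):
            raise ValueError("base formula cannot be deprotonated")


@dataclass(frozen=True)
class TruthRecord:
    name: str
    formula: MolecularFormula | None
    compound_class: str
    series_id: int | None = None


@dataclass(frozen=True)
class GroundTruth:
    records: Mapping[str, TruthRecord]

    def __getitem__(self, fid: str) -> TruthRecord:
        return self.records[fid]

    def ids_of_class(self, compound_class: str) -> list[str]:
        return sorted(
            fid for fid, r in self.records.items()
            if r.compound_class == compound_class
        )


def _anion_mz(neutral: MolecularFormula) -> float:
    return ion_mz(neutral - _H, -1)


def _spectrum(fid, precursor, fragments, losses, rng) -> Spectrum:
    mzs, ints = [], []
    for mz, inten in fragments:
        mzs.append(mz + rng.normal(0.0, 0.002))
        ints.append(inten * math.exp(rng.normal(0.0, 0.05)))
    for loss, inten in losses:
        mzs.append(precursor - loss + rng.normal(0.0, 0.002))
        ints.append(inten * math.exp(rng.normal(0.0, 0.05)))
    return Spectrum(fid, precursor, np.array(mzs), np.array(ints))


def generate(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[list[Feature], list[Spectrum], list[SeedAnnotation], GroundTruth]:
    """Generate (features, spectra, seeds, ground truth) from ``spec``.

    Deterministic for a fixed ``spec.seed``.  Seeds are the aglycone
    series members with their neutral formulas — the propagation target
    classes (glyco-variants, decoys) are never seeded.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_chain_lengths
    features: list[Feature] = []
    spectra: list[Spectrum] = []
    seeds: list[SeedAnnotation] = []
    truth: dict[str, TruthRecord] = {}
    covered: list[tuple[str, float, str, int]] = []  # id, precursor, kind, k

    def obs_mz(true_mz: float) -> float:
        return true_mz * (1.0 + rng.normal(0.0, spec.mz_noise_ppm * 1e-6))

    # aglycone series
    member_mz: list[float] = []
    for k in range(n):
        formula = spec.base_formula + spec.unit.delta_formula * k
        name = f"GPNAE {spec.base_chain + k}:0"
        fid = f"F{k + 1:03d}"
        true_mz = _anion_mz(formula)
        member_mz.append(true_mz)
        rt = spec.rt_intercept + spec.rt_slope * k + rng.normal(0, spec.rt_jitter)
        features.append(Feature(fid, obs_mz(true_mz), rt,
                                float(rng.lognormal(12, 0.5)), "negative"))
        truth[fid] = TruthRecord(name, formula, "GPNAE", series_id=1)
        seeds.append(SeedAnnotation(fid, name, formula, "GPNAE"))
        covered.append((fid, true_mz, "member", k))

    # glyco variants of a deterministic, seeded subset of members
    n_glyco = int(round(spec.glyco_fraction * n))
    glyco_ks = sorted(rng.choice(n, size=n_glyco, replace=False).tolist())
    glyco_series = 2 if n_glyco >= 4 else None
    for k in glyco_ks:
        formula = spec.base_formula + spec.unit.delta_formula * k + _HEXOSE
        name = f"GlycoGPNAE {spec.base_chain + k}:0"
        fid = f"G{k + 1:03d}"
        true_mz = _anion_mz(formula)
        rt = (spec.rt_intercept + spec.glyco_rt_offset + spec.rt_slope * k
              + rng.normal(0, spec.rt_jitter))
        features.append(Feature(fid, obs_mz(true_mz), max(rt, 1.0),
                                float(rng.lognormal(11, 0.5)), "negative"))
        truth[fid] = TruthRecord(name, formula, "GlycoGPNAE", glyco_series)
        covered.append((fid, true_mz, "glyco", k))

    # isomeric decoys: same m/z as a member, RT offset 60-120 s, LPE-like
    # spectra.  Isomers share the molecular formula by definition.
    decoy_ks = [k % n for k in range(spec.decoy_isomers)]
    for i, k in enumerate(decoy_ks):
        formula = spec.base_formula + spec.unit.delta_formula * k
        name = f"LPE {spec.base_chain + k - 3}:0"
        fid = f"D{i + 1:03d}"
        true_mz = member_mz[k]
        rt = (spec.rt_intercept + spec.rt_slope * k
              + float(rng.uniform(60.0, 120.0)))
        features.append(Feature(fid, obs_mz(true_mz), rt,
                                float(rng.lognormal(11, 0.5)), "negative"))
        truth[fid] = TruthRecord(name, formula, "LPE", None)
        covered.append((fid, true_mz, "decoy", k))

    # unrelated noise singletons (MS1 only)
    for i in range(spec.noise_features):
        fid = f"N{i + 1:03d}"
        features.append(
            Feature(fid, float(rng.uniform(150.0, 900.0)),
                    float(rng.uniform(60.0, 600.0)),
                    float(rng.lognormal(10, 0.5)), "negative")
        )
        truth[fid] = TruthRecord("noise", None, "noise", None)

    # MS2 spectra for a seeded ms2_coverage fraction of real features
    for fid, precursor, kind, k in covered:
        if rng.random() >= spec.ms2_coverage:
            continue
        if kind == "member":
            spectra.append(_spectrum(fid, precursor, _BACKBONE_FRAGMENTS,
                                     _NEUTRAL_LOSSES, rng))
        elif kind == "glyco":
            damped = [(mz, inten * 0.28) for mz, inten in _BACKBONE_FRAGMENTS]
            losses = [(loss, inten * 0.8) for loss, inten in _NEUTRAL_LOSSES[:2]]
            spectra.append(_spectrum(fid, precursor,
                                     damped + _GLUCOSE_FRAGMENTS, losses, rng))
        else:  # decoy
            spectra.append(_spectrum(fid, precursor, _DECOY_FRAGMENTS,
                                     [(140.0118, 40.0)], rng))
    return features, spectra, seeds, GroundTruth(truth)


@dataclass(frozen=True)
class EvaluationReport:
    precision: float
    recall: float
    per_class: Mapping[str, tuple[float, float]]
    decoy_hit_rate: float
    n_formula_annotations: int


def evaluate(
    resolved: Iterable,
    truth: GroundTruth,
    exclude_ids: Iterable[str] = (),
) -> EvaluationReport:
    """Precision/recall of propagated formulas against the ground truth.

    Precision: fraction of formula-bearing annotations (on features the
    truth knows) whose formula equals the true formula.  Recall:
    fraction of non-noise, non-excluded truth features with a formula
    that received a correct formula annotation.  Decoy hits — formula
    annotations landing on isomeric decoys — are reported separately;
    being isomers they match the formula, which is precisely the
    documented hazard.
    """
    excluded = set(exclude_ids)
    assigned: dict[str, set[str]] = {}
    for a in resolved:
        if a.formula is not None and a.feature_id not in excluded:
            assigned.setdefault(a.feature_id, set()).add(str(a.formula))

    n_pred = n_correct = 0
    per_class_counts: dict[str, list[int]] = {}
    for fid, formulas in assigned.items():
        rec = truth.records.get(fid)
        if rec is None:
            continue
        for f in formulas:
            n_pred += 1
            ok = rec.formula is not None and str(rec.formula) == f
            n_correct += int(ok)
            c = per_class_counts.setdefault(rec.compound_class, [0, 0, 0])
            c[0] += 1
            c[1] += int(ok)

    per_class: dict[str, tuple[float, float]] = {}
    recall_num = recall_den = 0
    for cls in sorted({r.compound_class for r in truth.records.values()}):
        targets = [
            fid for fid, r in truth.records.items()
            if r.compound_class == cls and r.formula is not None
            and fid not in excluded
        ]
        hit = sum(
            1 for fid in targets
            if str(truth.records[fid].formula) in assigned.get(fid, set())
        )
        counts = per_class_counts.get(cls, [0, 0, 0])
        prec = counts[1] / counts[0] if counts[0] else float("nan")
        rec_rate = hit / len(targets) if targets else float("nan")
        per_class[cls] = (prec, rec_rate)
        if cls not in ("noise", "LPE"):
            recall_num += hit
            recall_den += len(targets)

    decoys = [fid for fid in truth.ids_of_class("LPE") if fid not in excluded]
    decoy_hits = sum(1 for fid in decoys if assigned.get(fid))
    return EvaluationReport(
        precision=n_correct / n_pred if n_pred else float("nan"),
        recall=recall_num / recall_den if recall_den else float("nan"),
        per_class=per_class,
        decoy_hit_rate=decoy_hits / len(decoys) if decoys else float("nan"),
        n_formula_annotations=n_pred,
    )
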