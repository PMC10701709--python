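"""Annotation propagation from seed nodes over the merged typed graph.

Starting from a set of manually annotated seed features, annotations
are propagated to first neighbours along every edge of the merged
network.  The connecting edge's type set becomes the annotation's
"level" — the evidence classes (spectral similarity, mass difference,
homologous series) supporting it.  Where the edge carries a matched
mass difference and the seed has a molecular formula, the neighbour's
formula is the seed formula plus or minus the transformation's formula
delta, the sign taken from the precursor m/z ordering (heavier
neighbour = gain).  Second neighbours are annotated only across edges
supported by all three networks (configurable), propagating from the
first neighbour's resolved annotation; there is no iterative closure.

Multiple candidate annotations for one feature are resolved by keeping,
per distinct predicted formula, the candidate with the most supporting
network types, breaking ties by the smallest transformation mass and
then deterministically.  Candidates that predict different formulas for
one feature are all kept and flagged as conflicting.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .formula import InfeasibleTransformation, MolecularFormula, apply_transformation
from .io import SeedAnnotation
from .merge import MergedNetwork, TypedEdge

__all__ = [
    "PropagatedAnnotation",
    "propagate",
    "resolve",
    "summarize_levels",
    "cross_validate",
    "CrossValidationReport",
    "FoldResult",
    "LEVEL_ORDER",
]

#: canonical order for printing level combinations
LEVEL_ORDER = ("spectral", "massdiff", "homolog")


@dataclass(frozen=True)
class PropagatedAnnotation:
    """One (candidate or resolved) propagated annotation."""

    feature_id: str
    seed_id: str
    name: str
    level: frozenset[str]
    formula: MolecularFormula | None = None
    hop: int = 1
    cosine: float | None = None
    transformation: str | None = None
    delta_mass: float | None = None
    series_id: int | None = None
    conflict: bool = False

    def level_key(self) -> str:
        return "+".join(t for t in LEVEL_ORDER if t in self.level)


def _edge_values(edge: TypedEdge) -> dict:
    return {
        "cosine": edge.cosine,
        "series_id": edge.series_ids[0] if edge.series_ids else None,
    }


def _candidates_from(
    net: MergedNetwork,
    source_id: str,
    source_name: str,
    source_formula: MolecularFormula | None,
    seed_root: str,
    neighbor_id: str,
    edge: TypedEdge,
    hop: int,
) -> list[PropagatedAnnotation]:
    level = frozenset(edge.types)
    vals = _edge_values(edge)
    common = dict(feature_id=neighbor_id, seed_id=seed_root, level=level,
                  hop=hop, **vals)
    out: list[PropagatedAnnotation] = []
    if "massdiff" in level and edge.transformations and source_formula is not None:
        heavier = net.features[neighbor_id].mz > net.features[source_id].mz
        sign = 1 if heavier else -1
        op = "+" if heavier else "-"
        for mde in edge.transformations:
            t = mde.transformation
            try:
                formula = apply_transformation(source_formula, t, sign)
            except InfeasibleTransformation:
                continue
            out.append(
                PropagatedAnnotation(
                    name=f"{source_name} {op} {t.name}",
                    formula=formula,
                    transformation=t.name,
                    delta_mass=t.delta_mass,
                    **common,
                )
            )
    if not out:
        # no formula derivable (no massdiff evidence, seed without formula,
        # or every subtraction infeasible): spectral/homolog evidence still
        # places the neighbour in the seed's class.
        if level - {"massdiff"} or "massdiff" not in level:
            out.append(PropagatedAnnotation(name=source_name, **common))
    return out


def propagate(
    net: MergedNetwork,
    seeds: Sequence[SeedAnnotation],
    second_neighbor_min_types: int = 3,
) -> list[PropagatedAnnotation]:
    """Generate candidate annotations for first and second neighbours.

    Seeds themselves are never (re)annotated: manual annotations are
    authoritative, and seed-to-seed edges contribute nothing.  Second
    neighbours qualify only through an edge carrying at least
    ``second_neighbor_min_types`` network types (default 3 = all), and
    inherit from the first neighbour's *resolved* annotation.
    Propagation stops at two hops.
    """
    if not seeds:
        raise ValueError("seed node set is empty")
    missing = sorted({s.feature_id for s in seeds} - set(net.features))
    if missing:
        raise KeyError(f"seed ids not in graph: {missing}")
    seed_ids = {s.feature_id for s in seeds}

    first_hop: list[PropagatedAnnotation] = []
    for seed in sorted(seeds, key=lambda s: s.feature_id):
        for nbr in net.neighbors(seed.feature_id):
            if nbr in seed_ids:
                continue
            edge = net.edge(seed.feature_id, nbr)
            first_hop.extend(
                _candidates_from(net, seed.feature_id, seed.name, seed.formula,
                                 seed.feature_id, nbr, edge, hop=1)
            )

    second_hop: list[PropagatedAnnotation] = []
    for ann in resolve(first_hop):
        for nbr in net.neighbors(ann.feature_id):
            if nbr in seed_ids:
                continue
            edge = net.edge(ann.feature_id, nbr)
            if len(edge.types) < second_neighbor_min_types:
                continue
            second_hop.extend(
                _candidates_from(net, ann.feature_id, ann.name, ann.formula,
                                 ann.seed_id, nbr, edge, hop=2)
            )
    return first_hop + second_hop


def resolve(raw: Iterable[PropagatedAnnotation]) -> list[PropagatedAnnotation]:
    """Reduce candidates to at most one annotation per (feature, formula).

    Per group the surviving candidate has the largest level (most
    network types); ties go to the smallest transformation mass, then to
    hop, seed id and transformation name for determinism.  Features
    whose surviving annotations disagree on a (non-empty) formula keep
    them all, flagged ``conflict``.
    """
    groups: dict[tuple[str, str | None], list[PropagatedAnnotation]] = {}
    for a in raw:
        key = (a.feature_id, str(a.formula) if a.formula else None)
        groups.setdefault(key, []).append(a)

    survivors: list[PropagatedAnnotation] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1] or "")):
        cands = groups[key]
        cands.sort(
            key=lambda a: (
                -len(a.level),
                a.delta_mass if a.delta_mass is not None else float("inf"),
                a.hop,
                a.seed_id,
                a.transformation or "",
            )
        )
        survivors.append(cands[0])

    by_feature: dict[str, list[int]] = {}
    for i, a in enumerate(survivors):
        by_feature.setdefault(a.feature_id, []).append(i)
    for fid, idxs in by_feature.items():
        formulas = {str(survivors[i].formula) for i in idxs if survivors[i].formula}
        if len(formulas) > 1:
            for i in idxs:
                if survivors[i].formula is not None:
                    survivors[i] = replace(survivors[i], conflict=True)
    return survivors


def summarize_levels(resolved: Iterable[PropagatedAnnotation]) -> dict[str, int]:
    """Count annotations per evidence-level combination.

    Returns the seven level combinations plus ``total`` (all surviving
    annotations), ``multiple`` (features carrying more than one
    surviving annotation) and ``multiple_conflicting`` (features whose
    surviving annotations disagree on the formula).
    """
    combos = [
        "+".join(c)
        for n in (3, 2, 1)
        for c in itertools.combinations(LEVEL_ORDER, n)
    ]
    counts = {c: 0 for c in combos}
    per_feature: dict[str, list[PropagatedAnnotation]] = {}
    total = 0
    for a in resolved:
        counts[a.level_key()] += 1
        per_feature.setdefault(a.feature_id, []).append(a)
        total += 1
    counts["total"] = total
    counts["multiple"] = sum(1 for v in per_feature.values() if len(v) > 1)
    counts["multiple_conflicting"] = sum(
        1 for v in per_feature.values()
        if len({str(a.formula) for a in v if a.formula}) > 1
    )
    return counts


@dataclass(frozen=True)
class FoldResult:
    left_out: tuple[str, ...]
    recovered: tuple[bool, ...]


@dataclass(frozen=True)
class CrossValidationReport:
    folds: tuple[FoldResult, ...]
    n_evaluated: int
    n_recovered: int

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_evaluated if self.n_evaluated else 0.0


def cross_validate(
    net: MergedNetwork,
    seeds: Sequence[SeedAnnotation],
    k: int = 1,
    max_folds: int | None = None,
    rng_seed: int = 0,
    second_neighbor_min_types: int = 3,
) -> CrossValidationReport:
    """Leave-k-out cross-validation of formula recovery.

    Every size-``k`` subset of the seed set (or a random sample of
    ``max_folds`` of them) is withheld; propagation runs with the
    reduced seed set, and a withheld seed counts as recovered when some
    resolved annotation on its feature carries exactly its manual
    formula.
    """
    if not 1 <= k < len(seeds):
        raise ValueError("need len(seeds) > k >= 1")
    folds = list(itertools.combinations(sorted(seeds, key=lambda s: s.feature_id), k))
    if max_folds is not None and len(folds) > max_folds:
        folds = random.Random(rng_seed).sample(folds, max_folds)
    results = []
    n_eval = n_rec = 0
    for left_out in folds:
        out_ids = {s.feature_id for s in left_out}
        reduced = [s for s in seeds if s.feature_id not in out_ids]
        resolved = resolve(propagate(net, reduced, second_neighbor_min_types))
        by_id: dict[str, set[str]] = {}
        for a in resolved:
            if a.formula is not None:
                by_id.setdefault(a.feature_id, set()).add(str(a.formula))
        rec = tuple(
            s.formula is not None and str(s.formula) in by_id.get(s.feature_id, set())
            for s in left_out
        )
        results.append(FoldResult(tuple(s.feature_id for s in left_out), rec))
        n_eval += len(rec)
        n_rec += sum(rec)
    return CrossValidationReport(tuple(results), n_eval, n_rec)
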