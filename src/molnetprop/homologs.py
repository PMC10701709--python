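"""Homologous-series detection from m/z and retention-time trends.

A homologous series is a chain of features differing by a constant
repeating unit (e.g. CH2 at 14.0157 u) whose retention time moves
consistently in one direction along the chain — the signature of, say,
acyl-chain elongation under reversed-phase separation.  Chains are
assembled greedily on the pairwise step graph; a feature may belong to
more than one series.

Default constraints: unit mass in [5, 60] Da (with a 5 Da tolerance on
the range bounds), consecutive m/z gaps equal within 5 mDa, consecutive
RT shifts in [12, 60] s (with a 5 s tolerance on the bounds) and of the
same sign throughout, at least 4 members per series, and the unit must
be explainable by a formula over C, H and O only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formula import ELEMENT_MASSES, MolecularFormula
from .io import Feature

__all__ = ["SeriesParams", "SeriesCluster", "find_homologous_series", "homolog_edges"]


@dataclass(frozen=True)
class SeriesParams:
    """Tunable constraints of the series search (units: u and seconds)."""

    min_unit: float = 5.0
    max_unit: float = 60.0
    range_tol: float = 5.0  # tolerance on the [min_unit, max_unit] bounds
    unit_tol: float = 0.005  # within-series gap-consistency tolerance
    min_rt_shift: float = 12.0
    max_rt_shift: float = 60.0
    rt_tol: float = 5.0  # tolerance on the RT-shift bounds
    min_members: int = 4
    cho_only: bool = True
    cho_tol: float = 0.005  # tolerance for matching the unit to a CHO formula

    def __post_init__(self) -> None:
        if min(self.min_unit, self.max_unit, self.unit_tol, self.min_rt_shift,
               self.max_rt_shift, self.rt_tol) <= 0 or self.min_members < 2:
            raise ValueError("series parameters must be positive")


@dataclass(frozen=True)
class SeriesCluster:
    """One detected series: members ordered by ascending m/z."""

    series_id: int
    member_ids: tuple[str, ...]
    unit_mass: float
    unit_formula: MolecularFormula | None = None

    def __len__(self) -> int:
        return len(self.member_ids)


def _cho_candidates(lo: float, hi: float) -> list[tuple[float, MolecularFormula]]:
    mc, mh, mo = ELEMENT_MASSES["C"], ELEMENT_MASSES["H"], ELEMENT_MASSES["O"]
    out = []
    for c, h, o in itertools.product(range(6), range(13), range(5)):
        if c + h + o == 0:
            continue
        m = c * mc + h * mh + o * mo
        if lo <= m <= hi:
            out.append((m, MolecularFormula({"C": c, "H": h, "O": o})))
    out.sort()
    return out


def _match_cho(unit: float, candidates, tol: float) -> MolecularFormula | None:
    best, best_dev = None, tol
    for m, f in candidates:
        dev = abs(m - unit)
        if dev <= best_dev:
            best, best_dev = f, dev
    return best


def find_homologous_series(
    features: Sequence[Feature] | Iterable[Feature],
    params: SeriesParams = SeriesParams(),
) -> list[SeriesCluster]:
    """Detect homologous series among ``features`` (one polarity).

    Every ordered pair within the unit-mass and RT windows seeds a
    candidate chain; the chain is extended greedily, at each step taking
    the feature whose m/z gap is closest to the chain's unit (ties by
    feature id) among those satisfying the RT constraints with a
    consistent shift sign.  Maximal chains of at least ``min_members``
    become clusters; chains contained in an accepted chain are dropped,
    but partially overlapping chains are all kept.
    """
    feats = sorted(features, key=lambda f: (f.mz, f.id))
    lo = params.min_unit - params.range_tol
    hi = params.max_unit + params.range_tol
    rt_lo = max(params.min_rt_shift - params.rt_tol, 0.0)
    rt_hi = params.max_rt_shift + params.rt_tol
    cho = _cho_candidates(lo, hi) if params.cho_only else []

    def rt_ok(shift: float, sign: int) -> bool:
        return rt_lo <= sign * shift <= rt_hi

    def extend(chain: list[Feature], unit: float, sign: int) -> list[Feature]:
        while True:
            last = chain[-1]
            target = last.mz + unit
            best = None
            best_key = (params.unit_tol, "")
            for f in feats:
                if f.id in {c.id for c in chain}:
                    continue
                dev = abs(f.mz - target)
                if dev > params.unit_tol:
                    continue
                if not rt_ok(f.rt - last.rt, sign):
                    continue
                key = (dev, f.id)
                if key < best_key or best is None:
                    best, best_key = f, key
            if best is None:
                return chain
            chain.append(best)

    accepted: list[tuple[tuple[str, ...], float]] = []
    seen: set[tuple[str, ...]] = set()
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            unit = b.mz - a.mz
            if unit < lo:
                continue
            if unit > hi:
                break
            shift = b.rt - a.rt
            sign = 1 if shift >= 0 else -1
            if not rt_ok(shift, sign):
                continue
            if params.cho_only and _match_cho(unit, cho, params.cho_tol) is None:
                continue
            chain = extend([a, b], unit, sign)
            if len(chain) < params.min_members:
                continue
            ids = tuple(f.id for f in chain)
            if ids in seen:
                continue
            seen.add(ids)
            accepted.append((ids, unit))

    # drop chains that are contiguous sub-chains of a longer accepted chain
    accepted.sort(key=lambda t: (-len(t[0]), t[0]))
    kept: list[tuple[tuple[str, ...], float]] = []
    for ids, unit in accepted:
        contained = False
        for kids, _ in kept:
            if len(ids) < len(kids):
                s = "," + ",".join(ids) + ","
                if s in "," + ",".join(kids) + ",":
                    contained = True
                    break
        if not contained:
            kept.append((ids, unit))

    kept.sort(key=lambda t: t[0])
    clusters = []
    for sid, (ids, unit) in enumerate(kept, start=1):
        formula = _match_cho(unit, cho, params.cho_tol) if params.cho_only else None
        clusters.append(SeriesCluster(sid, ids, unit, formula))
    return clusters


def homolog_edges(clusters: Iterable[SeriesCluster]) -> list[tuple[str, str, int]]:
    """Edges between consecutive series members: (id_a, id_b, series_id)."""
    out = []
    for c in clusters:
        for a, b in zip(c.member_ids, c.member_ids[1:]):
            out.append((a, b, c.series_id))
    return out
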