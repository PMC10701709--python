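"""Mass-difference network: pairwise precursor differences vs a
transformation list.

Edges connect feature pairs whose m/z difference matches a listed
biochemical transformation within a ppm window anchored on the heavier
feature's m/z.  Retention time is deliberately not used here — isomer
disambiguation is left to the spectral and homologous-series layers,
which is why isomeric features (same m/z, different RT) end up
connected to the same partners.  This is a documented hazard of the
method, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formula import Transformation, TransformationList, match_mass_difference
from .io import Feature

__all__ = ["MassDiffEdge", "build_massdiff_network"]


@dataclass(frozen=True)
class MassDiffEdge:
    """One matched transformation between two features; ``id_a`` is the
    lighter feature, so ``observed_delta = mz_b - mz_a >= 0``."""

    id_a: str
    id_b: str
    transformation: Transformation
    observed_delta: float
    deviation: float


def build_massdiff_network(
    features: Sequence[Feature] | Iterable[Feature],
    transformations: TransformationList,
    ppm: float = 10.0,
) -> list[MassDiffEdge]:
    """Match every unordered feature pair against the transformation list.

    A pair matching several transformations yields several parallel
    candidate edges; the network merger later collapses them onto one
    typed edge carrying the full candidate list.  Default tolerance is
    10 ppm (qToF); use 5 ppm for Orbitrap data.
    """
    if ppm <= 0:
        raise ValueError("ppm must be positive")
    feats = sorted(features, key=lambda f: (f.mz, f.id))
    edges: list[MassDiffEdge] = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            light, heavy = feats[i], feats[j]
            delta = heavy.mz - light.mz
            for t in match_mass_difference(delta, heavy.mz, transformations, ppm):
                edges.append(
                    MassDiffEdge(
                        light.id, heavy.id, t, delta, abs(delta - t.delta_mass)
                    )
                )
    return edges
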