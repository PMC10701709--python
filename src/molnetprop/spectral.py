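"""Modified-cosine spectral similarity and the spectral network builder.

The modified cosine extends the plain spectral cosine by letting a
fragment of one spectrum match a fragment of the other when their m/z
differ by the precursor m/z difference, so that spectra of structurally
related compounds (e.g. a metabolite and its glycoside) still score
high even though many fragments are mass-shifted.

Intensities are square-root scaled by default before L2 normalisation
(the convention of feature-based molecular networking); the exponent is
configurable.  The score is a one-to-one peak matching: each fragment
may be used at most once.  Two solvers are provided — a fast greedy
assignment (default) and an exact maximum-weight matching via the
rectangular linear sum assignment problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import Spectrum

__all__ = ["SpectralEdge", "modified_cosine", "build_spectral_network"]


@dataclass(frozen=True)
class SpectralEdge:
    """Undirected spectral-similarity edge, stored with id_a < id_b."""

    id_a: str
    id_b: str
    cosine: float
    matched_peaks: int

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("self-edges are not allowed")
        if self.id_a > self.id_b:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)
        if not 0.0 <= self.cosine <= 1.0 + 1e-12:
            raise ValueError(f"cosine {self.cosine} outside [0, 1]")


def _candidate_pairs(
    a: Spectrum, b: Spectrum, frag_tol: float, allow_shift: bool
) -> np.ndarray:
    """Boolean matrix of allowed peak matches (direct or precursor-shifted)."""
    diff = np.abs(a.mz[:, None] - b.mz[None, :])
    allowed = diff <= frag_tol
    if allow_shift:
        shift = b.precursor_mz - a.precursor_mz
        allowed |= np.abs(a.mz[:, None] + shift - b.mz[None, :]) <= frag_tol
    return allowed


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    allow_shift: bool = True,
    intensity_power: float = 0.5,
    method: Literal["greedy", "exact"] = "greedy",
) -> tuple[float, int]:
    """Modified cosine score and number of matched fragment pairs.

    Parameters
    ----------
    frag_tol
        Fragment mass tolerance in u (default 0.02, typical for qToF).
    allow_shift
        Allow matches offset by the precursor m/z difference; ``False``
        gives the plain cosine.
    intensity_power
        Exponent applied to intensities before normalisation (0.5 =
        square-root scaling, 1.0 = raw intensities).
    method
        ``"greedy"``: descending-weight greedy assignment.  ``"exact"``:
        maximum-weight one-to-one matching (optimal).
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cannot score an empty spectrum")

    wa = a.intensities**intensity_power
    wb = b.intensities**intensity_power
    na = np.linalg.norm(wa)
    nb = np.linalg.norm(wb)
    if na == 0 or nb == 0:
        return 0.0, 0

    allowed = _candidate_pairs(a, b, frag_tol, allow_shift)
    if not allowed.any():
        return 0.0, 0
    weights = np.where(allowed, wa[:, None] * wb[None, :], 0.0)

    if method == "exact":
        rows, cols = linear_sum_assignment(weights, maximize=True)
        picked = weights[rows, cols]
        score = float(picked.sum()) / (na * nb)
        matched = int(np.count_nonzero(picked > 0))
    elif method == "greedy":
        order = np.argsort(weights, axis=None, kind="stable")[::-1]
        used_a = np.zeros(a.n_peaks, dtype=bool)
        used_b = np.zeros(b.n_peaks, dtype=bool)
        total = 0.0
        matched = 0
        for flat in order:
            i, j = divmod(int(flat), b.n_peaks)
            w = weights[i, j]
            if w <= 0:
                break
            if used_a[i] or used_b[j]:
                continue
            used_a[i] = used_b[j] = True
            total += w
            matched += 1
        score = total / (na * nb)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(float(score), 1.0), matched


def build_spectral_network(
    spectra: Sequence[Spectrum] | Iterable[Spectrum],
    frag_tol: float = 0.02,
    min_cosine: float = 0.8,
    min_matched: int = 3,
    top_k: int = 1000,
    allow_shift: bool = True,
    intensity_power: float = 0.5,
    method: Literal["greedy", "exact"] = "greedy",
) -> list[SpectralEdge]:
    """All-pairs spectral network with cosine, matched-ion and mutual
    top-k neighbour filters; no component-size pruning.

    An edge survives iff cosine >= ``min_cosine``, matched fragment
    pairs >= ``min_matched``, and each endpoint ranks the other within
    its ``top_k`` best neighbours by cosine (ties broken by smaller
    feature id).  The default top_k of 1000 is effectively
    non-restrictive at typical dataset sizes.
    """
    spectra = list(spectra)
    if any(p <= 0 for p in (frag_tol, min_cosine, top_k)) or min_matched <= 0:
        raise ValueError("all spectral-network parameters must be positive")
    candidates: list[SpectralEdge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            a, b = spectra[i], spectra[j]
            if a.feature_id == b.feature_id:
                raise ValueError(f"duplicate spectrum id {a.feature_id!r}")
            cos, matched = modified_cosine(
                a, b, frag_tol, allow_shift, intensity_power, method
            )
            if cos >= min_cosine and matched >= min_matched:
                candidates.append(SpectralEdge(a.feature_id, b.feature_id, cos, matched))

    # mutual top-k filter
    neighbours: dict[str, list[tuple[float, str]]] = {}
    for e in candidates:
        neighbours.setdefault(e.id_a, []).append((e.cosine, e.id_b))
        neighbours.setdefault(e.id_b, []).append((e.cosine, e.id_a))
    rank: dict[tuple[str, str], int] = {}
    for node, nbrs in neighbours.items():
        nbrs.sort(key=lambda t: (-t[0], t[1]))
        for r, (_, other) in enumerate(nbrs):
            rank[(node, other)] = r
    return [
        e
        for e in candidates
        if rank[(e.id_a, e.id_b)] < top_k and rank[(e.id_b, e.id_a)] < top_k
    ]
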