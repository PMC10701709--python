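import itertools

import numpy as np
import pytest

from molnetprop import Feature, FixtureSpec, Spectrum, generate


def make_spectrum(fid, precursor, peaks):
    mz, inten = zip(*peaks)
    return Spectrum(fid, precursor, np.array(mz, float), np.array(inten, float))


def random_spectrum(rng, fid, n_peaks=5, mz_range=(50.0, 500.0)):
    mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    inten = rng.uniform(1.0, 100.0, size=n_peaks)
    precursor = float(rng.uniform(mz_range[1], mz_range[1] + 300.0))
    return Spectrum(fid, precursor, mz, inten)


def brute_force_modified_cosine(a, b, frag_tol=0.02, allow_shift=True, power=0.5):
    """Exhaustive maximum over all one-to-one peak matchings (oracle)."""
    wa = a.intensities**power
    wb = b.intensities**power
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    shift = b.precursor_mz - a.precursor_mz
    allowed = {}
    for i in range(a.n_peaks):
        js = []
        for j in range(b.n_peaks):
            direct = abs(a.mz[i] - b.mz[j]) <= frag_tol
            shifted = allow_shift and abs(a.mz[i] + shift - b.mz[j]) <= frag_tol
            if direct or shifted:
                js.append(j)
        allowed[i] = js

    def best(i, used):
        if i == a.n_peaks:
            return 0.0
        score = best(i + 1, used)  # leave peak i unmatched
        for j in allowed[i]:
            if j not in used:
                score = max(score, wa[i] * wb[j] + best(i + 1, used | {j}))
        return score

    return best(0, frozenset()) / norm if norm else 0.0


def brute_force_massdiff(features, transformations, ppm):
    """O(n^2 * |list|) reference for the mass-difference builder."""
    edges = set()
    for fa, fb in itertools.combinations(features, 2):
        light, heavy = sorted([fa, fb], key=lambda f: (f.mz, f.id))
        delta = heavy.mz - light.mz
        for t in transformations:
            if abs(delta - t.delta_mass) <= ppm * 1e-6 * heavy.mz:
                edges.add((light.id, heavy.id, t.name))
    return edges


@pytest.fixture(scope="session")
def default_fixture():
    """Deterministic synthetic dataset with full MS2 coverage."""
    return generate(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def low_coverage_fixture():
    """The low-MS2-coverage regime: 30% of real features carry spectra."""
    return generate(FixtureSpec(seed=11, ms2_coverage=0.3))


@pytest.fixture
def toy_features():
    return [
        Feature("A", 400.0, 100.0),
        Feature("B", 414.0157, 130.0),
        Feature("C", 428.0313, 160.0),
    ]
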