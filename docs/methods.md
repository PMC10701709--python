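# Methods

## The annotation-propagation model

`molnetprop` treats a non-targeted LC-MS/MS dataset as a graph whose
nodes are aligned MS¹ features (id, *m/z*, retention time, intensity,
polarity) and whose edges come from three independent experimental
networks. Each network captures a different, partially overlapping
notion of "these two features are chemically related":

1. **Spectral similarity.** The modified cosine between two MS²
   spectra. Fragment peaks match either directly (|Δ*m/z*| ≤ `frag_tol`)
   or offset by the precursor *m/z* difference; the score is a
   one-to-one matching of normalised intensity products, so each peak is
   used at most once. An edge survives if cosine ≥ `min_cosine`, the
   matching uses ≥ `min_matched` fragment pairs, and the endpoints are
   mutually within each other's `top_k` best neighbours. Component size
   is never pruned.
2. **Mass difference.** For every unordered feature pair the precursor
   difference is compared with a list of biochemical transformations;
   each match within `ppm · 1e-6 · m/z(heavier)` adds a candidate edge.
   Retention time is deliberately not used here: isomer disambiguation
   is the job of the other two layers, and the resulting isomer
   connections are a documented hazard that the tests reproduce rather
   than hide.
3. **Homologous series.** Chains of features separated by a constant
   repeating unit explainable by a C/H/O formula, with consecutive
   retention-time shifts inside a window and of consistent sign — the
   chromatographic signature of, e.g., acyl-chain elongation on a
   reversed-phase column.

The three edge sets are merged on feature id into one typed graph: one
edge per pair, its `types` attribute recording the contributing
networks and all per-type evidence retained. Propagation then walks
from each manually annotated seed to its non-seed neighbours: the edge
type set becomes the annotation *level*; where the edge carries a
matched transformation and the seed has a formula, the neighbour
receives seed-formula ± transformation-delta (heavier neighbour =
gain), and the name is extended with "± ⟨transformation⟩". A neighbour
whose only support is a mass difference that cannot be subtracted
(element counts would go negative) keeps the spectral/homolog class
evidence but no formula. Second neighbours are reached only across
edges carrying all three types (configurable to ≥ 2), inheriting from
the first neighbour's resolved annotation; propagation stops at two
hops — there is no iterative closure, which keeps errors from
compounding along chains of inferences.

Competing candidates on one feature are grouped by predicted formula
(or by its absence). Within a group the annotation supported by the
most network types wins; ties go to the smallest transformation mass
("the simplest explanation"), then to hop, seed id and transformation
name so that reruns are byte-identical. Groups with different formulas
all survive, flagged as conflicts — the tool surfaces ambiguity instead
of guessing.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `ppm` | 10 | ppm | qToF-class mass accuracy; use 5 for Orbitrap data |
| `frag_tol` | 0.02 | u | fragment matching tolerance for MS² |
| `min_cosine` | 0.8 | – | spectral edge threshold |
| `min_matched` | 3 | ions | minimum matched fragment pairs |
| `top_k` | 1000 | – | mutual-rank cap; effectively unrestrictive at study scale |
| series unit range | 5–60 (±5) | Da | allowed repeating-unit masses |
| series unit consistency | 0.005 | u | within-chain gap equality |
| series RT shift | 12–60 (±5) | s | per-step retention shift window |
| series members | ≥ 4 | – | minimum chain length |
| second-neighbour rule | 3 types | – | strictest reading; configurable to ≥ 2 |

The ppm window is anchored on the heavier feature's *m/z*: the error of
a difference of two measured values scales with the measurements, and
the heavier anchor is the conservative symmetric choice.

The published operating point quotes a 5 Da "tolerance" on the
repeating-unit *m/z* difference. Taken literally as a unit-matching
tolerance it would merge every series (CH₂ and C₂H₄ would be
indistinguishable), so it is interpreted here as a tolerance on the
*range bounds* (units accepted in [5−5, 60+5] Da), with a separate
tight 5 mDa tolerance for gap equality within a chain. Both are
configurable.

Intensities are square-root scaled before normalisation in the cosine
(the feature-based molecular-networking convention); the exponent is a
parameter, and the test suite cross-checks the exponent-1 variant
against matchms' independent implementation. The default matching
solver is greedy (descending weight); an exact maximum-weight matching
via `scipy.optimize.linear_sum_assignment` is available and is what the
oracle tests and the acceptance script use. The greedy score is never
above the exact one; on small, well-separated spectra the two agree.

Element monoisotopic masses come from the NIST table shipped with
pyteomics. Ion *m/z* includes the electron mass
(`(M − z·mₑ)/|z|`); the measured negative-mode reference values
(171.0064 for [C₃H₈O₆P]⁻, 410.2313 for [C₁₈H₃₇NO₇P]⁻, 79.9668 for the
metaphosphate anion) are reproduced only with the electron term. Note
that 79.9668 is the *anion* of HPO₃ (79.9663 neutral); the commonly
written "[H₂PO₃]⁻" label would compute to 80.9747 and is treated as a
labelling slip, not as a target.

Two transformation lists ship with the package — 27 entries oriented at
GPNAE metabolism and 21 at ascaroside/modular-glucoside metabolism,
covering the transformations these chemistries are known for (CH₂,
C₂H₄, C₂H₂, H₂, O, HPO₃, C₂H₄O, C₃H₆O, C₅H₆O, C₆H₁₀O₅, C₁₃H₂₂O₅,
C₉H₅NO, …). They are plain `name,formula` CSVs, validated at load
(delta mass recomputed from the formula, 1 µu agreement required) and
meant to be replaced for other chemistries.

## The synthetic study and what it shows

The generator emulates the structure such a workflow is designed for: a
homologous series of [M−H]⁻ features (default: six members,
C₁₈H₃₈NO₇P + k·CH₂, RT = 300 + 30·k s with 2 s jitter, 2 ppm Gaussian
mass error), hexose variants for a fraction of members whose spectra
damp the shared backbone fragments (79.9669, 152.9958, 171.0064 and
precursor-relative neutral losses) and add internal glucose fragments
(59.0133, 89.0239, 101.0244, 119.0708) so that the plain cosine to the
aglycone falls well below the 0.8 threshold, isomeric decoys (identical
*m/z*, RT 60–120 s later, unrelated head-group fragments), a
configurable MS² coverage fraction, and random noise singletons. All
randomness flows from one seed; the ground truth records every
feature's identity, formula, class and series membership.

Spectra are kept small (6–9 peaks) so the exhaustive matching oracle in
the tests stays cheap; the end-to-end study sizes (22 features, 6
seeds, ≤ 15 cross-validation folds) were chosen so the full suite runs
in seconds while still exercising every propagation rule.

What passing on this fixture shows: the builders find exactly the
planted structure, propagation recovers every withheld seed formula
(leave-one-out and leave-two-out, 100 %), glyco-variants are annotated
without MS², and decoys are annotated *and* separable by their level
attribute. What it does not show: behaviour on real chromatography
(co-elution, in-source fragments, adduct diversity), spectra with
hundreds of noisy peaks, or transformation lists whose entries collide
within the ppm window — on real data the mass-difference layer is
noisier and the conflict flags matter far more.

## Numerical and degenerate-input choices

- Formula strings print in Hill order; parsing round-trips exactly.
  Charges are never encoded in formula strings.
- Zero-count elements are dropped, so formula equality is
  composition equality; subtraction below zero raises a typed
  "infeasible transformation" error that the propagation layer catches
  to skip that direction.
- A Δ*m/z* of 0 matches no transformation (all deltas are positive).
- Empty spectra are rejected at construction; peakless MGF blocks are
  skipped with a warning; spectra whose feature id resolves to nothing
  are dropped with a warning before network construction.
- Mixed-polarity inputs are split and processed per ionization mode.
- Top-*k* ranking ties break by smaller feature id; edge pairs are
  stored with the lexicographically smaller id first; every output
  table is sorted, making runs deterministic byte for byte.
- Cross-validation enumerates all size-*k* seed subsets and can sample
  a fixed number of folds with a seeded RNG when the binomial count is
  large.

## Known limitations

- A homologous series is only found if (nearly) all its members were
  detected; a single missing intermediate splits the chain, and chains
  shorter than `min_members` vanish entirely.
- Mass-difference edges connect isomers indiscriminately; the level
  attribute flags, but does not remove, such annotations.
- Formulas propagate only along mass-difference edges; spectral-only
  neighbours receive class membership, not a formula.
- Adducts and isotopologues are not deconvoluted; the feature table is
  assumed to carry one ion species per compound.
- The CLI's `build` subcommand performs construction and merging in one
  step; there is no separate `merge` stage because the merge is cheap
  and has no independent inputs.
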