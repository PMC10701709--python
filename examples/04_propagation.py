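"""Propagate seed annotations across the merged network."""

from molnetprop import (
    FixtureSpec,
    RunConfig,
    build_merged_network,
    generate,
    propagate,
    resolve,
    summarize_levels,
)

features, spectra, seeds, truth = generate(
    FixtureSpec(seed=1, ms2_coverage=0.3)  # low-MS2-coverage regime
)
net, *_ = build_merged_network(features, spectra, None, RunConfig())
resolved = resolve(propagate(net, seeds))

print(f"{len(seeds)} seeds -> {len(resolved)} propagated annotations")
for a in resolved:
    f = str(a.formula) if a.formula else "-"
    print(f"  {a.feature_id}: {a.name:28s} {f:14s} level={a.level_key()}")

print("\nlevel summary:")
for key, value in summarize_levels(resolved).items():
    print(f"  {key}: {value}")

# With 30% MS2 coverage most features never enter the spectral network,
# yet the glyco-variants are still annotated (+ Hexose, with a propagated
# formula) because mass-difference edges need only MS1 data.  The isomeric
# decoys are annotated too — at level 'massdiff' only, which is exactly
# the attribute a user filters on to treat them with caution.
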