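"""Build the three experimental networks and merge them into one graph."""

from collections import Counter

from molnetprop import FixtureSpec, RunConfig, build_merged_network, generate

features, spectra, seeds, truth = generate(FixtureSpec(seed=1))
net, n_spectral, n_massdiff, n_series = build_merged_network(
    features, spectra, transformations=None, config=RunConfig()
)

print(f"features: {net.n_nodes}  (spectra for {len(spectra)})")
print(f"spectral edges:        {n_spectral}")
print(f"massdiff candidates:   {n_massdiff}")
print(f"homologous series:     {n_series}")
print(f"merged typed edges:    {net.n_edges}")

type_mix = Counter(",".join(sorted(e.types)) for e in net.edges.values())
for types, count in sorted(type_mix.items()):
    print(f"  {types}: {count}")

# Each merged edge records which networks contained the pair.  Edges seen
# by several networks (e.g. spectral+massdiff+homolog) carry the strongest
# evidence and are the only ones trusted for second-neighbour propagation.
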