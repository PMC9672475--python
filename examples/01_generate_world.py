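"""Generate a synthetic two-species benchmark world and write its files.

The generator plants known structure: TLM genes with short/long knockout
phenotypes, phenotype-associated pathways and complexes, a PPI network
where TLM genes sit near anchor genes, and ortholog pairs with a known
phenotype-conservation probability.  Every file the pipeline reads is
emitted; ground_truth.json records what was planted.
"""

from pathlib import Path

from tlmnet.synthetic import WorldParams, generate_world, write_world

out = Path("scratch/example_world")
params = WorldParams(seed=1)
world = generate_world(params)
manifest = write_world(world, out)

print(f"wrote {len(manifest)} files to {out}/")
for name in sorted(manifest):
    print(f"  {name}")
print(
    f"\nplanted: {len(world.cerevisiae.tlm_phenotype)} budding-yeast and "
    f"{len(world.pombe.tlm_phenotype)} fission-yeast TLM genes "
    f"({len(world.cerevisiae.masked)} / {len(world.pombe.masked)} masked as unknown), "
    f"{len(world.true_orthologs)} ortholog pairs."
)
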