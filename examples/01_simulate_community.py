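"""Simulate a two-group rumen-like community with planted effects.

Builds a synthetic metagenome: species with KO-set genomes, NB gene counts
for 6 control (TP) and 6 treatment (US) samples, scaffolds, quality-scored
bins and an environment table.  Prints the planted truth the later stages
are asked to recover.
"""

from nicomm import generate_community

bundle = generate_community(
    n_species=12,
    seed=0,
    effect_spec={"S01": 8.0, "S03": 8.0, "S05": 0.125, "S07": 0.125},
)

print(f"genes x samples: {bundle.gene_counts.shape}")
print(f"scaffolds: {len(bundle.scaffold_table)}, bins: {len(bundle.bin_table)}")
print(f"marker genes planted: {len(bundle.sequences)}")
print("\nplanted fold-changes (treatment vs control):")
print(bundle.truth.effect_table[bundle.truth.effect_table != 1.0].to_string())
print("\nexpected directions on the relative (TPM) scale:")
print(bundle.truth.expected_relative_directions().to_string())
# Unperturbed species are expected 'downregulated' here: TPM is relative,
# so planting two strong 8-fold increases pushes every other species down.
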