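"""Generate a synthetic study: tree, trait histories, proteomes, hit table.

The generator plants two binary traits (an NHEJ repair system and a type
II-A CRISPR-Cas system) evolving on a Yule tree under a strongly negative
dependent regime, genome sizes correlated with the repair trait, and toy
proteomes with known ortholog families.
"""

from cooccurevo import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=42))

counts = ds.traits.joint_counts()
print(f"tips: {ds.tree.n_tips}")
print(f"joint trait counts (NHEJ, II-A): {counts}")
print(f"mean genome size with NHEJ:    "
      f"{ds.genome_table.loc[ds.genome_table['NHEJ'] == 1, 'size_bp'].mean():,.0f} bp")
print(f"mean genome size without NHEJ: "
      f"{ds.genome_table.loc[ds.genome_table['NHEJ'] == 0, 'size_bp'].mean():,.0f} bp")
print(f"hit-table rows: {len(ds.hit_table)}")

# The (1,1) count is near zero by construction: the dependent regime
# suppresses gaining either system while the other is present.  NHEJ
# genomes are drawn larger, planting the size confounder the statistics
# must handle.
ds.write("scratch/demo_dataset")
print("written to scratch/demo_dataset/")
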