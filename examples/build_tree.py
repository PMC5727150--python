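"""Build and import trees for the correlated-evolution test.

A tree can come from the package itself (p-distances on a concatenated
alignment + neighbor joining, see persistent_genome.py), from the Yule
simulator, or from any external program via Newick import.
"""

from cooccurevo import read_newick, write_newick
from cooccurevo.synthetic import simulate_tree

sim = simulate_tree(n_taxa=8, birth_rate=1.0, seed=3)
print(f"simulated Yule tree ({sim.n_tips} tips, {sim.n_internal} internal nodes):")
print(write_newick(sim))

imported = read_newick("((A:0.12,B:0.10):0.05,(C:0.08,D:0.15):0.03);")
print(f"\nimported tree: {imported.n_tips} tips, "
      f"bifurcating: {imported.is_bifurcating()}")
depths = imported.tip_depths()
print("root-to-tip depths:", {k: round(v, 3) for k, v in sorted(depths.items())})
# Any rooted bifurcating Newick tree with branch lengths works downstream;
# multifurcations are resolved into zero-length bifurcations on demand.
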