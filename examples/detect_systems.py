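"""Call NHEJ and type II CRISPR-Cas systems from a profile-hit table.

Detection is quorum-based: a system is present when a co-localized gene
cluster carries enough mandatory components (Ku for NHEJ; cas1+cas2+cas9
for type II).  Subtypes come from marker genes: csn2 -> II-A, cas4 ->
II-B, core genes only -> II-C.
"""

import pandas as pd

from cooccurevo import ProfileHitTable, detect_system, packaged_model

hits = ProfileHitTable(pd.DataFrame(
    [
        # genome 1: full NHEJ operon plus a II-A cas operon
        ("G1", "chromosome", 120, "Ku", 61.0),
        ("G1", "chromosome", 121, "LigD", 55.0),
        ("G1", "chromosome", 800, "cas9", 88.0),
        ("G1", "chromosome", 801, "cas1", 72.0),
        ("G1", "chromosome", 802, "cas2", 64.0),
        ("G1", "chromosome", 803, "csn2", 51.0),
    ],
    columns=["genome_id", "replicon", "gene_rank", "component", "score"],
))

nhej = detect_system(hits, packaged_model("nhej"))
cas = detect_system(hits, packaged_model("cas_type_ii"), classify_subtype=True)

print(f"NHEJ present: {nhej.present}  components: {sorted(nhej.components_found)}")
print(f"type II present: {cas.present}  subtype: {cas.subtype}  "
      f"components: {sorted(cas.components_found)}")
# G1 carries both systems: the single co-occurrence pattern the
# comparative analysis treats as exceptional.
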