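# Type II CRISPR-Cas operon: the three core genes (cas1, cas2, cas9) are
# mandatory; the subtype markers csn2 (II-A) and cas4 (II-B) are accessory
# and drive subtype classification.  This model encodes only the core-gene
# + subtype-marker logic; the full quorum rules of published detection
# models are richer and not reproduced here.
name: cas_type_II
mandatory: [cas1, cas2, cas9]
accessory: [csn2, cas4]
forbidden: []
min_mandatory: 3
colocalization_window: 5
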