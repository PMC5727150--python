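"""Run the whole analysis in one call and print the combined report.

simulate -> detect systems -> trait table -> co-occurrence statistics ->
correlated-evolution test, with every number collected in a Report that
is identical across reruns with the same seed.
"""

from cooccurevo.pipeline import demo_config, run

report = run(demo_config(seed=42), outdir="scratch/pipeline_run")
print(report.to_markdown())
# report.json, report.md, the dataset and the tree are all under
# scratch/pipeline_run/.
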