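"""Generate a planted-signal synthetic DTI benchmark and audit its composition.

The generator plants a low-rank drug x protein interaction signal and draws
heterogeneous annotation edges so that entities with similar latent factors
share annotations.  The audit verifies the protein-heavy edge composition
(the fraction of supporting information that is protein-related, 0.83 by
default) and summarizes degrees and top betweenness centrality.
"""

from kgenfm import synth

bench = synth.generate(synth.SynthConfig(seed=0))
report = synth.audit(bench)

print(f"entities: {len(bench.kg.entities())}, triples: {len(bench.kg)}")
print(f"DTI positives: {len(bench.positives)}")
print(f"relation counts: {report.relation_counts}")
print(f"protein-related fraction of heterogeneous edges: "
      f"{report.protein_fraction:.3f} (configured {bench.config.protein_fraction})")
print(f"degree summary: {report.degree_summary}")
print("top betweenness:", report.top_betweenness[:3])
# The fraction should sit within +-0.02 of the knob; without a planted hub no
# node should dominate shortest paths (normalized betweenness stays low).
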