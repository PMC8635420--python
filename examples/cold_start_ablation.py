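"""Compare warm start vs cold start for proteins, with and without KGE.

Cold-start proteins have no interaction edges at training time, only
heterogeneous annotations; the knowledge-graph embedding path is what lets
the model transfer to them, so the structure-only ablation should trail the
full model there.  AUPR is the primary metric under 10:1 imbalance.
"""

from kgenfm import experiments, synth

bench = synth.generate(synth.SynthConfig(seed=0))

for scenario, mode in [("warm", "full"),
                       ("cold_protein", "full"),
                       ("cold_protein", "structure_only")]:
    r = experiments.run_holdout(bench, scenario, mode, seed=0)
    print(f"{scenario:13s} {mode:15s} AUROC {r.auroc:.3f}  AUPR {r.aupr:.3f} "
          f"(test n={r.n_test})")
# Expected ordering: both full-model rows clearly beat the ~0.09 AUPR of a
# random ranker at 10:1 imbalance, and on cold proteins the full model beats
# the structure-only ablation.
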