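"""Movement-chain network of a simulated group of sharks.

Discretises detections into hourly node/absent states, pools the
transition counts over a group, and solves the stationary distribution
of the resulting Markov chain by power iteration -- the eigenvector-
centrality proxy for where an animal is most likely to be found.
"""

import atollnet as an
from atollnet.edmc import export_network, group_chain
from atollnet.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(
    seed=11, group_sizes={("F", "C"): 4}, max_duration_days=120, detection_prob=1.0
)
ds, truth = simulate_cohort(cfg)
ds = an.remove_false_detections(ds)
ds, _ = an.apply_minimum_days_filter(ds)
ds = an.merge_receiver_nodes(ds)

res = group_chain(ds, truth.sharks["shark_id"].tolist(), label="FC")
print(f"states: {len(res.states)} (16 nodes + ABSENT); "
      f"transitions counted: {res.counts.to_numpy().sum()}")
print(f"pi(ABSENT) = {res.centrality['ABSENT']:.3f} "
      "(probability of being outside every receiver's range)")
top = res.centrality.drop("ABSENT").sort_values(ascending=False).head(3)
print("top nodes by centrality:")
print(top.round(4).to_string())
print("node degrees (distinct neighbours with observed transitions):")
print(res.degrees[res.degrees > 0].to_string())

paths = export_network(res, "scratch/network_demo")
print(f"\nwrote {paths['edges']} and {paths['graphml']}")
print("High ABSENT centrality reproduces the sparse-array reality: animals "
      "spend most hours outside the ~250 m detection range of any receiver.")
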