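"""Continuation-phase dynamics: allele trajectories, LCA, plasmid frequency.

After the simulator's conjugation phase ends, populations drift (with
sweeps) for 200 further generations.  Comparing allele frequencies at the
two timepoints shows whether donor alleles behave like transient
deleterious variants (falling) or hitchhikers/beneficials (rising), and
alleles fixed at both timepoints and present in both clones reconstruct
the population's last-common-ancestor haplotype.
"""

import numpy as np

from introscan import dynamics, simulate as sim
from introscan.model import CoveragePair

result = sim.simulate_experiment(seed=41, n_populations=1, genome_length=150_000)[0]

t0 = sim.population_call_set(result, 0)
t1 = sim.population_call_set(result, 1)
trajectories = dynamics.frequency_change(t0, t1)
deltas = np.array([tr.delta for tr in trajectories])
up, down = (deltas > 0).sum(), (deltas < 0).sum()
print(
    f"{len(trajectories)} allele trajectories between the two timepoints: "
    f"{up} rose, {down} fell, mean change {deltas.mean():+.4f}"
)
print(
    "with conjugation off and no selection on donor alleles, rises and falls "
    "reflect drift and hitchhiking with sweeps, not a systematic donor-allele cost"
)

clone_a = sim.clone_call_set(result, result.clones[0][0])
clone_b = sim.clone_call_set(result, result.clones[1][0])
lca = dynamics.infer_lca(t0, t1, clone_a, clone_b, population_id=result.population_id)
print(
    f"LCA haplotype of {result.population_id}: {len(lca)} mutations fixed at both "
    "timepoints and carried by both sequenced clones"
)

print("plasmid frequency from relative coverage (one plasmid per carrier cell):")
for sample, chrom_cov, plasmid_cov in [
    ("gen-1000", 647.8, 3.0),
    ("gen-1200", 686.9, 250.3),
]:
    freq = dynamics.plasmid_frequency(CoveragePair(sample, chrom_cov, plasmid_cov))
    print(f"  {sample}: chromosome {chrom_cov}x, plasmid {plasmid_cov}x -> frequency {freq}")

p = 0.3
print(
    f"ratchet model: a neutral donor allele at frequency {p} fixes at the next "
    f"sweep with probability {dynamics.ratchet_fixation_probability(p)}"
)
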