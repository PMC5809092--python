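"""Parallel-introgression profile across simulated replicate populations.

Counts, at every donor-vs-recipient marker site, how many of 10 replicate
populations' clones carry the donor allele, smooths the profile with a
natural cubic spline, and checks the peak against the donors' oriT
geometry — introgression should concentrate where transfer probability is
highest.
"""

import numpy as np

from introscan import introgression as intro, provenance, simulate as sim

results = sim.simulate_experiment(seed=31, n_populations=10, genome_length=250_000)
landscape = results[0].landscape
L = landscape.genome_length

donors_cs = sim.donor_call_sets(landscape, results[0].donors)
labeled_by_clone = {}
for r in results:
    clone_id, _ = r.clones[0]
    labeled_by_clone[clone_id] = provenance.label_mutations(
        sim.clone_call_set(r, clone_id), sim.recipient_call_set(r), donors_cs, L
    )

profile = intro.parallel_introgression(
    labeled_by_clone, include_one_clone_per_population=False
)
print(
    f"profile over {len(profile.positions)} marker sites, "
    f"{profile.n_included} clones; max parallel count = {profile.counts.max()}"
)

smoothed = intro.smooth_profile(profile.positions, profile.counts, df=100)
peak = int(profile.positions[np.argmax(smoothed)])
print(f"smoothed-profile peak at position {peak}")
for d in results[0].donors:
    sign = 1 if d.orientation == "+" else -1
    dist = (sign * (peak - d.oriT_pos)) % L
    print(
        f"  {d.donor_id}: oriT at {d.oriT_pos} ({d.orientation}), "
        f"peak lies {dist} bp downstream in its transfer direction"
    )
print(
    "the peak should sit a short distance downstream of one oriT: transfer "
    "probability decays log-linearly with distance from the origin of transfer"
)

binning = intro.make_binning(L, 8327)
divergence = intro.DivergenceProfile.from_positions(landscape.positions, binning)
events = profile.per_bin(binning, reduce="sum")
tests = intro.divergence_tests(divergence, events, exact_spearman=False)
print(
    f"binned into {binning.n_bins} bins of 8327 bp: Spearman r = "
    f"{tests['spearman_r']:.4f} (p = {tests['spearman_p']:.3g}) between local marker "
    "density and introgression count; under uniform marker placement this is ~0"
)
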