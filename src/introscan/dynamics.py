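"""Continuation-experiment analytics.

After the recombination treatment stops, two-timepoint whole-population
sequencing shows whether introgressed donor alleles were transient
maladapted variants (frequencies fall), neutral hitchhikers, or beneficial
(frequencies rise).  This module computes per-site frequency trajectories,
infers the haplotype fixed in each population's last common ancestor, and
estimates plasmid frequency from relative sequencing coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import CoveragePair, GenomeCallSet, VariantSite

#: float-safety tolerance on "frequency equal to 1"
_FIXED_EPS = 1e-9


@dataclass(frozen=True)
class AlleleTrajectory:
    """Frequency of one allele at the two continuation timepoints."""

    site: VariantSite
    f0: float
    f1: float

    def __post_init__(self) -> None:
        for f in (self.f0, self.f1):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} outside [0, 1]")

    @property
    def delta(self) -> float:
        return self.f1 - self.f0

    @property
    def direction(self) -> str:
        """Above/below/on the diagonal of the f1-vs-f0 plot."""
        if self.delta > 0:
            return "up"
        if self.delta < 0:
            return "down"
        return "flat"


@dataclass(frozen=True)
class FixedHaplotype:
    """Mutations inferred fixed in a population's last common ancestor."""

    population_id: str
    sites: frozenset[VariantSite]

    def __contains__(self, site: VariantSite) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


def frequency_change(
    pop_t0: GenomeCallSet, pop_t1: GenomeCallSet
) -> list[AlleleTrajectory]:
    """One trajectory per site in the union of the two population samples.

    A site absent from one sample has frequency 0 there (the caller
    reports only variant sites).  Output is ordered by site identity.
    """
    from .model import site_sort_key

    union = pop_t0.sites | pop_t1.sites
    return [
        AlleleTrajectory(site, pop_t0.frequency(site), pop_t1.frequency(site))
        for site in sorted(union, key=site_sort_key)
    ]


def infer_lca(
    pop_t0: GenomeCallSet,
    pop_t1: GenomeCallSet,
    clone_a: GenomeCallSet,
    clone_b: GenomeCallSet,
    population_id: str | None = None,
) -> FixedHaplotype:
    """Mutations at frequency 1 at both timepoints and present in both clones.

    An allele fixed throughout the continuation interval and carried by
    both sequenced clones must have been present in the population's last
    common ancestor.  "Frequency equal to 1" is taken literally (within
    float tolerance); 0.98 does not qualify.
    """
    fixed0 = {s for s, f in pop_t0.variants.items() if f >= 1.0 - _FIXED_EPS}
    fixed1 = {s for s, f in pop_t1.variants.items() if f >= 1.0 - _FIXED_EPS}
    sites = fixed0 & fixed1 & clone_a.sites & clone_b.sites
    return FixedHaplotype(
        population_id=population_id or pop_t0.sample_id,
        sites=frozenset(sites),
    )


def round_2sig(x: float) -> float:
    """Round to two significant figures (0.004631 -> 0.0046, 0.3644 -> 0.36)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + 1)


def plasmid_frequency(cov: CoveragePair, rounded: bool = True) -> float:
    """Fraction of cells carrying the plasmid, from relative read coverage.

    Assumes one chromosome per cell and one plasmid per plasmid-bearing
    cell, so frequency = plasmid coverage / chromosome coverage.  Values
    above 1 indicate multi-copy carriage and are returned as-is (not
    clipped).  By default the estimate is rounded to two significant
    figures, the precision the coverage summaries support.
    """
    if cov.chrom_cov == 0:
        raise ValueError("chromosome coverage is zero")
    freq = cov.plasmid_cov / cov.chrom_cov
    return round_2sig(freq) if rounded else freq


def ratchet_fixation_probability(p: float) -> float:
    """Probability the next beneficial sweep fixes a neutral allele at frequency p.

    Under the ratchet-hitchhiking model a sweep originates on a single
    random genetic background, so a neutral donor-derived allele at
    frequency ``p`` hitchhikes to fixation with probability ``p`` and goes
    extinct with probability ``1 - p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    return p
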