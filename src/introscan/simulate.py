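"""Forward simulator of an Hfr-conjugation evolution experiment.

The generator reproduces the statistical structure the analysis modules
assume, with full ground truth:

* a circular reference chromosome carrying a dense landscape of
  donor-vs-recipient differentiating markers (~8 per kb, as between
  *E. coli* K-12 and B), a configurable fraction of which are private to
  one of four donor strains;
* four Hfr donors with distinct oriT positions/orientations and
  amino-acid auxotrophy mutations;
* unidirectional conjugative transfer whose extent decays log-linearly
  with distance from oriT (from ~10^-2.5 at the near anchor to ~10^-6 at
  the far anchor), truncated at the maximal transferable fraction of the
  chromosome;
* purifying selection that removes transconjugants acquiring any donor
  auxotrophy allele;
* Wright-Fisher drift between periodic conjugation pulses, with optional
  instantaneous selective sweeps that implement the ratchet-hitchhiking
  model (a sweep copies one random individual's haplotype to fixation, so
  a neutral allele at frequency p fixes with probability p);
* new point mutations and gene-conversion clusters decorated onto the
  sampled clones;
* a two-timepoint "continuation" phase with conjugation switched off.

Default scale is a 200 kb chromosome with decay anchors shrunk
proportionally, N = 1000, and 30 conjugation cycles of 33 generations —
small enough for routine runs while preserving the marker density and
transfer-decay geometry of the full-size experiment.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import GenomeCallSet, Role, VariantKind, VariantSite

REFERENCE_LENGTH = 4_629_812  # the full-size chromosome the anchors refer to
CHROM = "chr"


# ---------------------------------------------------------------------------
# parameters and donor models


@dataclass(frozen=True)
class ConjugationParams:
    """Transfer-decay and treatment parameters.

    ``p_100kb`` and ``p_2300kb`` anchor the log-linear decay of the
    probability that a locus at a given distance from oriT is transferred;
    ``d_near``/``d_far`` are the anchor distances in bp.  Transfer is
    impossible beyond ``max_fraction_transferred`` of the chromosome.
    """

    p_100kb: float = 10 ** -2.5
    p_2300kb: float = 1e-6
    d_near: float = 100_000.0
    d_far: float = 2_300_000.0
    donor_recipient_ratio: float = 4.0
    max_fraction_transferred: float = 0.6
    cycle_interval_generations: int = 33
    n_cycles: int = 30
    fragmentation_rate: float = 0.0  # per-kb probability of a tract break

    def __post_init__(self) -> None:
        if not (0 < self.p_2300kb < self.p_100kb <= 1):
            raise ValueError("require 0 < p_2300kb < p_100kb <= 1")
        if not (0 < self.max_fraction_transferred <= 1):
            raise ValueError("max_fraction_transferred must be in (0, 1]")
        if self.d_near >= self.d_far:
            raise ValueError("d_near must be < d_far")

    def scaled_to(self, genome_length: int) -> "ConjugationParams":
        """Shrink the anchor distances proportionally to a smaller chromosome."""
        f = genome_length / REFERENCE_LENGTH
        return replace(self, d_near=self.d_near * f, d_far=self.d_far * f)

    @property
    def attempts_per_recipient(self) -> float:
        """Mating attempts per recipient cell per conjugation pulse.

        With donors in excess each recipient encounters several donors
        during the mating hour; 2.5 encounters per unit of donor excess
        (10 attempts at the default 4:1 ratio) gives a cumulative
        near-oriT transfer fraction over a 30-pulse treatment of order
        one-half, matching the prevalence of near-oriT introgression the
        design is meant to produce.
        """
        return self.donor_recipient_ratio * 2.5


@dataclass(frozen=True)
class DonorModel:
    """One Hfr donor: transfer origin, orientation, and private markers."""

    donor_id: str
    oriT_pos: int
    orientation: str  # '+' transfers toward increasing coordinates
    auxotrophy_positions: tuple[int, ...]
    donor_specific_markers: frozenset[int]

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        for pos in self.auxotrophy_positions:
            if pos not in self.donor_specific_markers:
                raise ValueError("auxotrophy positions must be donor-specific marker sites")


@dataclass(frozen=True)
class MarkerLandscape:
    """The differentiating-marker sites of the reference chromosome."""

    genome_length: int
    positions: np.ndarray  # sorted, 1-based
    specific_owner: dict[int, str] = field(default_factory=dict)  # pos -> donor id

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def index_of(self, pos: int) -> int:
        i = int(np.searchsorted(self.positions, pos))
        if i >= len(self.positions) or self.positions[i] != pos:
            raise KeyError(pos)
        return i


def make_marker_landscape(
    genome_length: int,
    markers_per_kb: float = 8.0,
    specific_fraction: float = 0.1,
    donor_ids: Sequence[str] = ("REL288", "REL291", "REL296", "REL298"),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> MarkerLandscape:
    """Draw a uniform marker landscape at the requested density.

    The marker count is Poisson around ``density x length``; a
    ``specific_fraction`` of markers is assigned round-robin-free,
    uniformly at random, to single donors as donor-specific sites.
    """
    if markers_per_kb < 0:
        raise ValueError("density must be nonnegative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = rng.poisson(markers_per_kb * genome_length / 1000.0)
    n = min(n, genome_length)
    positions = np.sort(rng.choice(genome_length, size=n, replace=False) + 1)
    specific_owner: dict[int, str] = {}
    if n and specific_fraction > 0 and donor_ids:
        n_specific = int(round(specific_fraction * n))
        chosen = rng.choice(n, size=n_specific, replace=False)
        owners = rng.integers(0, len(donor_ids), size=n_specific)
        for idx, owner in zip(chosen, owners):
            specific_owner[int(positions[idx])] = donor_ids[owner]
    return MarkerLandscape(genome_length, positions, specific_owner)


def default_donors(
    landscape: MarkerLandscape,
    donor_ids: Sequence[str] = ("REL288", "REL291", "REL296", "REL298"),
    auxotrophy_offset_fraction: float = 0.3,
) -> list[DonorModel]:
    """Four donors with evenly spaced oriT sites and alternating orientations.

    Each donor's auxotrophy mutation is placed at its donor-specific
    marker nearest to a point ``auxotrophy_offset_fraction`` of the
    chromosome downstream of its own oriT, mimicking designs where the
    auxotrophy limits how much of a donor's high-transfer region can fix.
    """
    L = landscape.genome_length
    donors = []
    for k, donor_id in enumerate(donor_ids):
        oriT = int(L * (2 * k + 1) / (2 * len(donor_ids))) or 1
        orientation = "+" if k % 2 == 0 else "-"
        own = sorted(p for p, d in landscape.specific_owner.items() if d == donor_id)
        if not own:
            raise ValueError(f"no donor-specific markers for {donor_id}")
        sign = 1 if orientation == "+" else -1
        target = (oriT - 1 + sign * int(auxotrophy_offset_fraction * L)) % L + 1
        aux = min(own, key=lambda p: _circular_distance(p, target, L))
        donors.append(
            DonorModel(
                donor_id=donor_id,
                oriT_pos=oriT,
                orientation=orientation,
                auxotrophy_positions=(aux,),
                donor_specific_markers=frozenset(own),
            )
        )
    return donors


def _circular_distance(a: int, b: int, L: int) -> int:
    d = abs(a - b)
    return min(d, L - d)


# ---------------------------------------------------------------------------
# transfer law


def transfer_probability(
    distance_from_oriT: float, params: ConjugationParams, genome_length: int
) -> float:
    """Probability that a locus at the given distance downstream of oriT transfers.

    Log-linear through the two anchors, flat below the near anchor, zero
    beyond ``max_fraction_transferred x genome_length``.
    """
    if distance_from_oriT < 0:
        raise ValueError("distance must be nonnegative")
    cutoff = params.max_fraction_transferred * genome_length
    if distance_from_oriT > cutoff:
        return 0.0
    if distance_from_oriT <= params.d_near:
        return params.p_100kb
    lp1, lp2 = math.log10(params.p_100kb), math.log10(params.p_2300kb)
    slope = (lp2 - lp1) / (params.d_far - params.d_near)
    return 10 ** (lp1 + slope * (distance_from_oriT - params.d_near))


def sample_transfer_length(
    params: ConjugationParams, genome_length: int, rng: np.random.Generator
) -> int:
    """Draw a transferred-tract length whose survival function is the decay law.

    P(length >= d) equals :func:`transfer_probability` at distance d, so
    per-site Monte-Carlo transfer frequencies match the law exactly.  Most
    draws return 0 (the mating transfers nothing detectable).
    """
    u = rng.random()
    if u > params.p_100kb:
        return 0
    return _invert_decay(u, params, genome_length)


def _invert_decay(u: float, params: ConjugationParams, genome_length: int) -> int:
    """Tract length whose survival function matches the decay law, given u <= p_100kb."""
    cutoff = params.max_fraction_transferred * genome_length
    lp1, lp2 = math.log10(params.p_100kb), math.log10(params.p_2300kb)
    slope = (lp2 - lp1) / (params.d_far - params.d_near)
    d = params.d_near + (math.log10(u) - lp1) / slope
    return int(min(max(d, params.d_near), cutoff))


# ---------------------------------------------------------------------------
# haplotypes


@dataclass(frozen=True)
class Haplotype:
    """One cell's genotype over the tracked sites.

    ``markers`` holds, per marker site, which allele the cell carries:
    False = recipient/reference allele, True = donor (K-12) allele.
    ``ltee`` flags which of the recipient's evolved mutations are still
    present.  ``tracts`` is the true transfer history: tuples of
    ``(donor_id, start, end)`` 1-based inclusive circular intervals.
    """

    markers: bytes
    ltee: bytes
    tracts: tuple[tuple[str, int, int], ...] = ()

    def marker_array(self) -> np.ndarray:
        return np.frombuffer(self.markers, dtype=bool).copy()

    def ltee_array(self) -> np.ndarray:
        return np.frombuffer(self.ltee, dtype=bool).copy()


def founder_haplotype(landscape: MarkerLandscape, n_ltee: int) -> Haplotype:
    return Haplotype(
        markers=bytes(landscape.n_markers),
        ltee=bytes([1]) * n_ltee,
    )


def _circular_interval_mask(positions: np.ndarray, start: int, end: int, L: int) -> np.ndarray:
    """Boolean mask of positions inside the circular interval [start, end]."""
    if start <= end:
        return (positions >= start) & (positions <= end)
    return (positions >= start) | (positions <= end)


def conjugate(
    recipient_hap: Haplotype,
    donor: DonorModel,
    params: ConjugationParams,
    landscape: MarkerLandscape,
    ltee_positions: np.ndarray,
    rng: np.random.Generator,
    selection: bool = True,
    length: int | None = None,
):
    """One mating: returns ``(transconjugant, true_intervals)`` or ``None``.

    A tract starts at oriT and extends in the transfer direction to a
    length drawn from the decay law.  With ``fragmentation_rate > 0`` the
    tract is broken into mosaic pieces, alternately integrated and
    skipped.  Integration replaces recipient alleles across each
    integrated piece: marker sites take the donor's allele (which erases
    other donors' private alleles), and evolved recipient mutations inside
    the piece are lost.  With selection on, a transconjugant acquiring any
    of this donor's auxotrophy alleles is rejected (returns ``None``:
    purifying selection removes it immediately).
    """
    L = landscape.genome_length
    if length is None:
        length = sample_transfer_length(params, L, rng)
    if length <= 0:
        return None
    sign = 1 if donor.orientation == "+" else -1
    raw_start = donor.oriT_pos
    raw_end = (donor.oriT_pos - 1 + sign * (length - 1)) % L + 1
    if sign > 0:
        tract = (raw_start, raw_end)
    else:
        tract = (raw_end, raw_start)

    pieces: list[tuple[int, int]]
    if params.fragmentation_rate > 0:
        pieces = _fragment(tract, length, params.fragmentation_rate, L, rng)
    else:
        pieces = [tract]

    if selection:
        for a, b in pieces:
            for aux in donor.auxotrophy_positions:
                if _in_circular(aux, a, b, L):
                    return None

    markers = recipient_hap.marker_array()
    ltee = recipient_hap.ltee_array()
    pos = landscape.positions
    for a, b in pieces:
        mask = _circular_interval_mask(pos, a, b, L)
        idx = np.flatnonzero(mask)
        for i in idx:
            p = int(pos[i])
            owner = landscape.specific_owner.get(p)
            markers[i] = owner is None or owner == donor.donor_id
        if len(ltee_positions):
            ltee[_circular_interval_mask(ltee_positions, a, b, L)] = False
    new_tracts = recipient_hap.tracts + tuple(
        (donor.donor_id, a, b) for a, b in pieces
    )
    hap = Haplotype(markers=markers.tobytes(), ltee=ltee.tobytes(), tracts=new_tracts)
    return hap, [(donor.donor_id, a, b) for a, b in pieces]


def _in_circular(p: int, a: int, b: int, L: int) -> bool:
    if a <= b:
        return a <= p <= b
    return p >= a or p <= b


def _fragment(
    tract: tuple[int, int],
    length: int,
    rate_per_kb: float,
    L: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Split a tract at Poisson break points; keep alternating pieces."""
    n_breaks = rng.poisson(rate_per_kb * length / 1000.0)
    if n_breaks == 0:
        return [tract]
    offsets = np.sort(rng.integers(1, length, size=n_breaks))
    bounds = [0, *offsets.tolist(), length]
    a0 = tract[0]
    pieces = []
    for k in range(len(bounds) - 1):
        if k % 2 == 1:
            continue  # skipped (untouched) piece
        lo = (a0 - 1 + bounds[k]) % L + 1
        hi = (a0 - 1 + bounds[k + 1] - 1) % L + 1
        pieces.append((lo, hi))
    return pieces


# ---------------------------------------------------------------------------
# population dynamics


@dataclass
class PopulationState:
    """Haplotype counts at one generation."""

    counts: dict[Haplotype, int]
    generation: int = 0

    @property
    def size(self) -> int:
        return sum(self.counts.values())

    def marker_frequencies(self, n_markers: int) -> np.ndarray:
        freq = np.zeros(n_markers)
        N = self.size
        for hap, c in self.counts.items():
            freq += np.frombuffer(hap.markers, dtype=bool) * (c / N)
        return freq

    def ltee_frequencies(self, n_ltee: int) -> np.ndarray:
        freq = np.zeros(n_ltee)
        N = self.size
        for hap, c in self.counts.items():
            freq += np.frombuffer(hap.ltee, dtype=bool) * (c / N)
        return freq

    def heterozygosity(self) -> float:
        """Probability two random cells carry different haplotypes."""
        N = self.size
        return 1.0 - sum((c / N) ** 2 for c in self.counts.values())

    def sample_haplotypes(self, k: int, rng: np.random.Generator) -> list[Haplotype]:
        haps = list(self.counts)
        weights = np.array([self.counts[h] for h in haps], dtype=float)
        picks = rng.choice(len(haps), size=k, p=weights / weights.sum())
        return [haps[i] for i in picks]


def wright_fisher_step(state: PopulationState, rng: np.random.Generator) -> PopulationState:
    """One generation of multinomial resampling at constant size."""
    haps = list(state.counts)
    N = state.size
    probs = np.array([state.counts[h] for h in haps], dtype=float) / N
    new_counts = rng.multinomial(N, probs)
    return PopulationState(
        counts={h: int(c) for h, c in zip(haps, new_counts) if c > 0},
        generation=state.generation + 1,
    )


def apply_sweep(state: PopulationState, rng: np.random.Generator) -> PopulationState:
    """An instantaneous selective sweep: one random cell's haplotype fixes."""
    winner = state.sample_haplotypes(1, rng)[0]
    return PopulationState(counts={winner: state.size}, generation=state.generation)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic call sets."""

    tracts_by_clone: dict[str, list[tuple[str, int, int]]]
    transferred_markers_by_clone: dict[str, list[int]]
    new_mutation_positions_by_clone: dict[str, list[int]]
    fixed_marker_positions: list[int]
    conversions_by_clone: dict[str, list[tuple[str, list[int]]]] = field(
        default_factory=dict
    )


@dataclass
class SimResult:
    landscape: MarkerLandscape
    donors: list[DonorModel]
    ltee_positions: np.ndarray
    params: ConjugationParams
    state_t0: PopulationState
    state_t1: PopulationState
    clones: list[tuple[str, Haplotype]]
    truth: SimTruth
    snapshots: list[tuple[int, float]]  # (generation, heterozygosity)
    population_id: str = "pop"


def evolve_population(
    landscape: MarkerLandscape,
    donors: list[DonorModel],
    params: ConjugationParams,
    rng: np.random.Generator,
    population_size: int = 1000,
    n_ltee_mutations: int = 50,
    sweep_rate: float = 0.02,
    continuation_generations: int = 200,
    selection: bool = True,
    population_id: str = "pop",
    ltee_positions: np.ndarray | None = None,
) -> SimResult:
    """Run the full two-phase experiment for one population.

    Phase 1 (``n_cycles`` x ``cycle_interval_generations``): a conjugation
    pulse at the start of each cycle, Wright-Fisher drift each generation,
    sweeps at ``sweep_rate`` per generation.  Phase 2 (continuation):
    identical but with conjugation off.  Haplotype frequencies are
    recorded at the end of each phase, and two clones are sampled at the
    end of phase 1 (as in clone-resequencing designs).
    """
    if not donors:
        raise ValueError("need at least one donor model")
    L = landscape.genome_length
    if ltee_positions is None:
        marker_set = set(landscape.positions.tolist())
        free = np.setdiff1d(
            rng.integers(1, L + 1, size=20 * n_ltee_mutations), list(marker_set)
        )
        ltee_positions = np.sort(rng.choice(free, size=n_ltee_mutations, replace=False))
    founder = founder_haplotype(landscape, len(ltee_positions))
    state = PopulationState(counts={founder: population_size})
    snapshots: list[tuple[int, float]] = []

    n_phase1 = params.n_cycles * params.cycle_interval_generations
    total = n_phase1 + continuation_generations
    state_t0 = state
    clones: list[tuple[str, Haplotype]] = []
    for gen in range(total):
        conjugating = gen < n_phase1
        if conjugating and gen % params.cycle_interval_generations == 0:
            state = _conjugation_pulse(
                state, landscape, donors, params, ltee_positions, rng, selection
            )
        state = wright_fisher_step(state, rng)
        if sweep_rate > 0 and rng.random() < sweep_rate:
            state = apply_sweep(state, rng)
        if gen % params.cycle_interval_generations == 0:
            snapshots.append((state.generation, state.heterozygosity()))
        if state.generation == n_phase1:
            state_t0 = state
            haps = state.sample_haplotypes(2, rng)
            clones = [(f"{population_id}_clone{k + 1}", h) for k, h in enumerate(haps)]
    state_t1 = state

    freq0 = state_t0.marker_frequencies(landscape.n_markers)
    freq1 = state_t1.marker_frequencies(landscape.n_markers)
    fixed = np.flatnonzero((freq0 >= 1.0 - 1e-9) & (freq1 >= 1.0 - 1e-9))
    truth = SimTruth(
        tracts_by_clone={cid: list(h.tracts) for cid, h in clones},
        transferred_markers_by_clone={
            cid: landscape.positions[h.marker_array()].astype(int).tolist()
            for cid, h in clones
        },
        new_mutation_positions_by_clone={cid: [] for cid, _ in clones},
        fixed_marker_positions=landscape.positions[fixed].astype(int).tolist(),
    )
    return SimResult(
        landscape=landscape,
        donors=donors,
        ltee_positions=ltee_positions,
        params=params,
        state_t0=state_t0,
        state_t1=state_t1,
        clones=clones,
        truth=truth,
        snapshots=snapshots,
        population_id=population_id,
    )


def _conjugation_pulse(
    state: PopulationState,
    landscape: MarkerLandscape,
    donors: list[DonorModel],
    params: ConjugationParams,
    ltee_positions: np.ndarray,
    rng: np.random.Generator,
    selection: bool,
) -> PopulationState:
    """Each cell attempts matings with random donors; rejects stay parental.

    Only attempts that actually transfer DNA (probability ``p_100kb`` per
    attempt under the decay law) are materialized; each success converts
    one cell of its parental group, and a transconjugant rejected by
    auxotrophy selection reverts to the parental haplotype (immediate
    death and replacement by a sibling).
    """
    new_counts: dict[Haplotype, int] = {}
    for hap, count in state.counts.items():
        n_attempts = int(round(count * params.attempts_per_recipient))
        n_success = min(int(rng.binomial(n_attempts, params.p_100kb)), count)
        stay = count - n_success
        for _ in range(n_success):
            donor = donors[rng.integers(0, len(donors))]
            length = _invert_decay(
                rng.uniform(0.0, params.p_100kb), params, landscape.genome_length
            )
            result = conjugate(
                hap,
                donor,
                params,
                landscape,
                ltee_positions,
                rng,
                selection,
                length=length,
            )
            if result is None:
                stay += 1
            else:
                new_hap, _ = result
                new_counts[new_hap] = new_counts.get(new_hap, 0) + 1
        if stay:
            new_counts[hap] = new_counts.get(hap, 0) + stay
    return PopulationState(counts=new_counts, generation=state.generation)


# ---------------------------------------------------------------------------
# decoration of sampled clones with new mutations / gene conversions


def decorate_clone(
    result: SimResult,
    clone_id: str,
    rng: np.random.Generator,
    mean_new_mutations: float = 5.0,
    n_gene_conversions: int = 1,
    conversion_cluster_span: int = 1000,
) -> None:
    """Add de novo mutations and gene-conversion clusters to a sampled clone.

    New mutations land at positions that are neither marker nor evolved
    recipient sites.  A gene-conversion event plants >= 3 clustered new
    mutations inside a 1 kb window sharing one gene annotation, the
    signature the conversion detector looks for.  Truth is updated in
    place.
    """
    L = result.landscape.genome_length
    occupied = set(result.landscape.positions.tolist()) | set(
        result.ltee_positions.tolist()
    )
    new_positions: list[int] = []
    n_new = rng.poisson(mean_new_mutations)
    while len(new_positions) < n_new:
        p = int(rng.integers(1, L + 1))
        if p not in occupied:
            occupied.add(p)
            new_positions.append(p)
    conversions: list[tuple[str, list[int]]] = []
    for k in range(n_gene_conversions):
        anchor = int(rng.integers(1, L - conversion_cluster_span))
        size = int(rng.integers(3, 7))
        cluster: list[int] = []
        while len(cluster) < size:
            p = anchor + int(rng.integers(0, conversion_cluster_span))
            if p not in occupied:
                occupied.add(p)
                cluster.append(p)
        conversions.append((f"conv_gene_{k + 1}", sorted(cluster)))
    result.truth.new_mutation_positions_by_clone[clone_id] = sorted(
        new_positions + [p for _, cluster in conversions for p in cluster]
    )
    result.truth.conversions_by_clone[clone_id] = conversions


# ---------------------------------------------------------------------------
# call-set emission


_BASES = "ACGT"


def _marker_site(pos: int) -> VariantSite:
    return VariantSite(CHROM, pos, VariantKind.SNP, _BASES[pos % 4])


def _ltee_site(pos: int) -> VariantSite:
    return VariantSite(CHROM, pos, VariantKind.SNP, _BASES[(pos + 1) % 4])


def _new_site(pos: int, gene: str | None = None) -> VariantSite:
    return VariantSite(CHROM, pos, VariantKind.SNP, _BASES[(pos + 2) % 4], gene=gene)


def donor_call_sets(landscape: MarkerLandscape, donors: list[DonorModel]) -> list[GenomeCallSet]:
    """Each donor carries every shared marker plus its own private markers."""
    out = []
    for donor in donors:
        sites = []
        for pos in landscape.positions.tolist():
            owner = landscape.specific_owner.get(pos)
            if owner is None or owner == donor.donor_id:
                sites.append(_marker_site(pos))
        out.append(GenomeCallSet.from_sites(donor.donor_id, Role.DONOR, sites))
    return out


def recipient_call_set(result: SimResult, sample_id: str = "recipient") -> GenomeCallSet:
    sites = [_ltee_site(int(p)) for p in result.ltee_positions]
    return GenomeCallSet.from_sites(sample_id, Role.RECIPIENT, sites)


def clone_call_set(result: SimResult, clone_id: str) -> GenomeCallSet:
    hap = dict(result.clones)[clone_id]
    sites = [
        _marker_site(int(p))
        for p in result.landscape.positions[hap.marker_array()].tolist()
    ]
    sites += [
        _ltee_site(int(p))
        for p in result.ltee_positions[hap.ltee_array()].tolist()
    ]
    conv_positions = {
        p: gene
        for gene, cluster in result.truth.conversions_by_clone.get(clone_id, [])
        for p in cluster
    }
    for p in result.truth.new_mutation_positions_by_clone.get(clone_id, []):
        sites.append(_new_site(p, gene=conv_positions.get(p)))
    return GenomeCallSet.from_sites(clone_id, Role.RECOMBINANT, sites)


def population_call_set(
    result: SimResult, timepoint: int, sample_id: str | None = None
) -> GenomeCallSet:
    """Population allele-frequency sample at timepoint 0 or 1."""
    state = result.state_t0 if timepoint == 0 else result.state_t1
    marker_freq = state.marker_frequencies(result.landscape.n_markers)
    ltee_freq = state.ltee_frequencies(len(result.ltee_positions))
    callset = GenomeCallSet(
        sample_id or f"{result.population_id}_t{timepoint}", Role.POPULATION, {}
    )
    for p, f in zip(result.landscape.positions.tolist(), marker_freq):
        if f > 0:
            callset.add(_marker_site(int(p)), min(float(f), 1.0))
    for p, f in zip(result.ltee_positions.tolist(), ltee_freq):
        if f > 0:
            callset.add(_ltee_site(int(p)), min(float(f), 1.0))
    return callset


def emit(result: SimResult, out_dir: str) -> dict[str, str]:
    """Write all call sets, annotations, and truth files for one population.

    Clonal genomes go out as GenomeDiff files, population samples as VCF,
    donor annotations and the marker landscape as TSV/CSV, and ground
    truth as JSON.  Output is deterministic for a fixed simulation.
    """
    from . import io_tables

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    for cs in donor_call_sets(result.landscape, result.donors):
        p = os.path.join(out_dir, f"{cs.sample_id}.gd")
        io_tables.write_variant_table(cs, p)
        paths[cs.sample_id] = p
    rcs = recipient_call_set(result)
    paths["recipient"] = os.path.join(out_dir, "recipient.gd")
    io_tables.write_variant_table(rcs, paths["recipient"])
    for clone_id, _ in result.clones:
        cs = clone_call_set(result, clone_id)
        p = os.path.join(out_dir, f"{clone_id}.gd")
        io_tables.write_variant_table(cs, p)
        paths[clone_id] = p
    for t in (0, 1):
        cs = population_call_set(result, t)
        p = os.path.join(out_dir, f"{cs.sample_id}.vcf")
        io_tables.write_variant_table(cs, p)
        paths[cs.sample_id] = p

    anno_path = os.path.join(out_dir, "donor_annotations.csv")
    with open(anno_path, "w") as fh:
        fh.write("donor_id,oriT_pos,orientation,auxotrophy_positions\n")
        for d in result.donors:
            aux = ";".join(str(p) for p in d.auxotrophy_positions)
            fh.write(f"{d.donor_id},{d.oriT_pos},{d.orientation},{aux}\n")
    paths["donor_annotations"] = anno_path

    markers_path = os.path.join(out_dir, "marker_landscape.tsv")
    with open(markers_path, "w") as fh:
        fh.write("pos\tspecific_owner\n")
        for p in result.landscape.positions.tolist():
            fh.write(f"{p}\t{result.landscape.specific_owner.get(p, '')}\n")
    paths["marker_landscape"] = markers_path

    truth_path = os.path.join(out_dir, "truth.json")
    truth = {
        "genome_length": result.landscape.genome_length,
        "tracts_by_clone": result.truth.tracts_by_clone,
        "transferred_markers_by_clone": result.truth.transferred_markers_by_clone,
        "new_mutation_positions_by_clone": result.truth.new_mutation_positions_by_clone,
        "fixed_marker_positions": result.truth.fixed_marker_positions,
        "conversions_by_clone": result.truth.conversions_by_clone,
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = truth_path
    return paths


def simulate_experiment(
    seed: int,
    n_populations: int = 10,
    genome_length: int = 200_000,
    markers_per_kb: float = 8.0,
    population_size: int = 1000,
    params: ConjugationParams | None = None,
    sweep_rate: float = 0.02,
    continuation_generations: int = 200,
    selection: bool = True,
    decorate: bool = True,
) -> list[SimResult]:
    """Run the default multi-population scenario.

    One shared marker landscape and donor panel; independent populations
    evolved with per-population RNG streams derived from ``seed``.
    """
    root = np.random.default_rng(seed)
    params = (params or ConjugationParams()).scaled_to(genome_length)
    landscape = make_marker_landscape(genome_length, markers_per_kb, rng=root)
    donors = default_donors(landscape)
    results = []
    for k in range(n_populations):
        rng = np.random.default_rng(root.integers(0, 2**31))
        result = evolve_population(
            landscape,
            donors,
            params,
            rng,
            population_size=population_size,
            sweep_rate=sweep_rate,
            continuation_generations=continuation_generations,
            selection=selection,
            population_id=f"pop{k + 1}",
        )
        if decorate:
            for clone_id, _ in result.clones:
                decorate_clone(result, clone_id, rng)
        results.append(result)
    return results
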