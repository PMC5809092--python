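"""Genome-binned introgression profiles and divergence statistics.

The central object is the *parallel introgression profile*: for every
marker site that differentiates the donor strain background from the
recipient/reference background, the number of analyzed clones in which the
donor allele is present.  Regions of parallel introgression across
replicate populations point to transfer-probability gradients (distance
from oriT) and to selection.  Companion statistics test whether local
sequence divergence (marker density per bin) predicts where introgressions
or recombination breakpoints land.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .provenance import LabeledVariant, ProvenanceLabel
from .segments import AncestrySegment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width binning of [1, genome_length]; the last bin may be short.

    Bins are half-open ``[start, start + bin_size)`` in internal
    arithmetic and reported 1-based inclusive.
    """

    genome_length: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.bin_size < 1:
            raise ValueError("genome_length and bin_size must be >= 1")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.genome_length / self.bin_size)

    def bin_index(self, pos: int) -> int:
        if not 1 <= pos <= self.genome_length:
            raise ValueError(f"position {pos} outside [1, {self.genome_length}]")
        return (pos - 1) // self.bin_size

    def bin_bounds(self, index: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of bin ``index``."""
        start = index * self.bin_size + 1
        return start, min(start + self.bin_size - 1, self.genome_length)

    def count_per_bin(self, positions) -> np.ndarray:
        counts = np.zeros(self.n_bins, dtype=int)
        for p in positions:
            counts[self.bin_index(int(p))] += 1
        return counts


def make_binning(genome_length: int, bin_size: int) -> GenomeBinning:
    return GenomeBinning(genome_length, bin_size)


@dataclass
class IntrogressionProfile:
    """Per-site parallel introgression counts across included clones."""

    positions: np.ndarray  # sorted marker positions
    counts: np.ndarray  # clones carrying the donor allele at each position
    n_included: int
    excluded_populations: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos": self.positions, "count": self.counts})

    def per_bin(self, binning: GenomeBinning, reduce: str = "sum") -> np.ndarray:
        """Aggregate the profile per bin (``sum``, ``median`` or ``max``)."""
        idx = (self.positions - 1) // binning.bin_size
        out = np.zeros(binning.n_bins)
        fns = {"sum": np.sum, "median": np.median, "max": np.max}
        for b in range(binning.n_bins):
            vals = self.counts[idx == b]
            out[b] = fns[reduce](vals) if len(vals) else 0.0
        return out


def parallel_introgression(
    labeled_by_clone: dict[str, list[LabeledVariant]],
    population_of: dict[str, str] | None = None,
    include_one_clone_per_population: bool = True,
    exclude: list[str] | None = None,
) -> IntrogressionProfile:
    """Count, per differentiating marker site, how many clones carry the donor allele.

    ``population_of`` maps clone id -> population name.  When
    ``include_one_clone_per_population`` is set, the lexicographically
    first clone of each population is used.  Populations in ``exclude``
    (e.g. one almost entirely donor-derived) are dropped; an excluded name
    matching no clone logs a warning.
    """
    exclude = list(exclude or [])
    population_of = population_of or {c: c for c in labeled_by_clone}
    known_pops = set(population_of.values())
    for pop in exclude:
        if pop not in known_pops:
            logger.warning("excluded population %r not found", pop)
    by_pop: dict[str, list[str]] = {}
    for clone in sorted(labeled_by_clone):
        pop = population_of.get(clone, clone)
        if pop in exclude:
            continue
        by_pop.setdefault(pop, []).append(clone)
    included: list[str] = []
    for pop in sorted(by_pop):
        clones = by_pop[pop]
        included.extend(clones[:1] if include_one_clone_per_population else clones)

    counts: dict[tuple[str, int], int] = {}
    for clone in included:
        for lv in labeled_by_clone[clone]:
            if lv.primary_label is ProvenanceLabel.K12_MUTATION:
                key = (lv.site.chrom, lv.site.pos)
                counts[key] = counts.get(key, 0) + 1
            elif lv.label is ProvenanceLabel.REL606_MARKER:
                counts.setdefault((lv.site.chrom, lv.site.pos), 0)
    keys = sorted(counts)
    return IntrogressionProfile(
        positions=np.array([pos for _, pos in keys], dtype=int),
        counts=np.array([counts[k] for k in keys], dtype=int),
        n_included=len(included),
        excluded_populations=exclude,
    )


@dataclass
class DivergenceProfile:
    """Per-bin count of donor-vs-recipient differentiating markers."""

    binning: GenomeBinning
    counts: np.ndarray

    @classmethod
    def from_positions(cls, positions, binning: GenomeBinning) -> "DivergenceProfile":
        return cls(binning, binning.count_per_bin(positions))


def smooth_profile(positions, values, df: int = 100) -> np.ndarray:
    """Least-squares natural cubic spline fit with ``df`` basis functions.

    Knots sit at quantiles of ``positions``, so the fit is invariant to
    coordinate rescaling.  Returns the fitted value at every input
    position; the fit is deterministic (pure linear algebra).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(positions) < df + 1:
        raise ValueError(f"need at least df+1={df + 1} points, got {len(positions)}")
    basis = patsy.dmatrix(
        "cr(x, df=%d)" % df, {"x": positions}, return_type="matrix"
    )
    X = np.asarray(basis)
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return X @ coef


def divergence_tests(
    divergence: DivergenceProfile, events_per_bin, exact_spearman: bool | None = None
) -> dict[str, float | None]:
    """Does local divergence predict where events (introgressions/breakpoints) fall?

    Returns Spearman rank correlation of per-bin divergence with per-bin
    event counts, and a Kruskal–Wallis comparison of divergence between
    bins with and without events.  Correlations on constant vectors are
    reported as None.  With <= 8 bins (or ``exact_spearman=True``) the
    Spearman p-value is computed by exhaustive enumeration of pairings
    rather than the large-sample approximation.
    """
    div = np.asarray(divergence.counts, dtype=float)
    ev = np.asarray(events_per_bin, dtype=float)
    if len(div) != len(ev):
        raise ValueError("per-bin vectors must have equal length")
    if exact_spearman is None:
        exact_spearman = len(div) <= 8
    out: dict[str, float | None] = {}
    if np.ptp(div) == 0 or np.ptp(ev) == 0:
        out["spearman_r"] = None
        out["spearman_p"] = None
    else:
        r, p = stats.spearmanr(div, ev)
        if exact_spearman:
            # permute the pairing of one vector only: n! distinct pairings
            res = stats.permutation_test(
                (div,),
                lambda x: stats.spearmanr(x, ev).statistic,
                permutation_type="pairings",
                alternative="two-sided",
                n_resamples=np.inf,
            )
            p = res.pvalue
        out["spearman_r"] = float(r)
        out["spearman_p"] = float(p)
    with_ev = div[ev > 0]
    without_ev = div[ev == 0]
    if len(with_ev) and len(without_ev) and np.ptp(div) > 0:
        _, kw_p = stats.kruskal(with_ev, without_ev)
        out["kw_p"] = float(kw_p)
    else:
        out["kw_p"] = None
    return out


def breakpoints_per_bin(
    segments_by_clone: dict[str, list[AncestrySegment]],
    binning: GenomeBinning,
    genome_length: int,
) -> np.ndarray:
    """Count painted segment boundaries per bin.

    A boundary between two adjacent segments is an interval of uncertainty
    (the gap between the flanking markers); each boundary is assigned to
    the bin containing the midpoint of the realized painted boundary,
    i.e. the junction between consecutive segments.
    """
    counts = np.zeros(binning.n_bins, dtype=int)
    for segs in segments_by_clone.values():
        if len(segs) < 2:
            continue
        for seg in segs:
            junction = seg.end % genome_length + 1  # position after the segment
            counts[binning.bin_index(junction)] += 1
    return counts


def fixed_marker_profile(
    lca_sets: dict[str, set], exclude: list[str] | None = None
) -> IntrogressionProfile:
    """Parallel fixation counts over populations' LCA-fixed donor markers.

    ``lca_sets`` maps population -> set of VariantSite fixed in that
    population's inferred last common ancestor.  Counting is per site, as
    in :func:`parallel_introgression`, so the result is pointwise bounded
    by the clone-presence profile.
    """
    exclude = list(exclude or [])
    for pop in exclude:
        if pop not in lca_sets:
            logger.warning("excluded population %r not found", pop)
    included = [p for p in sorted(lca_sets) if p not in exclude]
    counts: dict[tuple[str, int], int] = {}
    for pop in included:
        for site in lca_sets[pop]:
            key = (site.chrom, site.pos)
            counts[key] = counts.get(key, 0) + 1
    keys = sorted(counts)
    return IntrogressionProfile(
        positions=np.array([pos for _, pos in keys], dtype=int),
        counts=np.array([counts[k] for k in keys], dtype=int),
        n_included=len(included),
        excluded_populations=exclude,
    )
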