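# Methods

This note documents the models and conventions behind `introscan`, the
parameters that matter, and what the synthetic-data tests do and do not
establish about real data.

## Setting

The package analyzes experiments in which auxotrophic Hfr donor strains
are periodically added to evolving recipient populations in minimal
medium. Donors transfer chromosomal DNA unidirectionally from an
integrated *oriT* site; they cannot grow (auxotrophy), so their genetic
contribution is purely horizontal. All genomes are represented as variant
calls against one shared circular reference chromosome; a site's identity
is `(chrom, pos, kind, alt)` with 1-based inclusive coordinates throughout
(identical to the VCF and GenomeDiff conventions, so no coordinate
conversion occurs at I/O boundaries).

## Provenance labeling

Labeling is deterministic set algebra per site over four collections:
recombinant R, recipient P, donor union D, and per-donor private sets.
With membership written (R, P, D):

| membership        | label            |
|-------------------|------------------|
| R ∩ P, ∉ D        | LTEE_MUTATION    |
| R ∩ D, ∉ P        | K12_MUTATION (donor-specific sub-label when private to one donor) |
| R only            | NEW_MUTATION     |
| D only            | REL606_MARKER    |
| P, ∉ R            | DELETED_MUTATION |
| R ∩ P ∩ D         | ignored (uninformative) |

Two conventions close gaps the category definitions leave open. First,
`K12_MUTATION` additionally requires absence from the recipient, so that
the categories are disjoint; a site shared by both parents carries no
donor-vs-recipient signal. Second, sites are checked against the
recombinant's called large deletions: a lost recipient mutation inside a
deletion gets `in_deleted_region=True` (lost with the region rather than
replaced allele-for-allele), and a donor-union marker inside a deleted
span is dropped with a logged count — a deleted region can support
neither ancestry. Indel and IS identity matching is exact on
`(pos, kind, alt)`; no fuzzy position merging is attempted, because input
tables are assumed to come from one caller on one reference.

## Ancestry painting

Painting reduces a recombinant to ordered two-state markers: at every
donor-vs-recipient differentiating site the clone carries either the
donor allele (K12 evidence) or the recipient allele (B evidence; these
are the `REL606_MARKER` sites absent from the recombinant). True
breakpoints fall in inter-marker gaps, so segment boundaries are only
known to that resolution. The rule used: a donor segment opens at its
first donor marker (minimal left estimate) and closes at the next
recipient marker (maximal right estimate); recipient segments are the
complement. The opposing biases make painted donor lengths approximate
the midpoint of the per-segment minimum and maximum estimates.

Conventions: on a circular chromosome the painting closes over the
origin, merging a shared state across position 1 into one wrapping
segment (the chromosome has no natural break). With no markers the whole
chromosome is painted recipient (clonal-frame default); with only one
marker type present, the whole chromosome takes that state. In linear
mode the region before the first marker takes the complement of a leading
donor run (a donor segment never extends left of its first marker) and a
trailing donor run extends to the end (its right bound is unconstrained).
When one donor tract's closing recipient marker immediately precedes the
next tract's opening donor marker, the zero-length recipient arc is
collapsed and the donor segments merge. Resolution is reported, not
modeled: each segment carries its supporting marker count, and no
probabilistic (HMM) smoothing is applied.

## Introgression profiles and statistics

The parallel-introgression profile counts, per differentiating site, the
clones (one per population by default, with configurable exclusions)
carrying the donor allele. Counting is per site, not per linked event;
adjacent markers on one transferred tract each contribute. Smoothing uses
least squares on a natural cubic regression spline basis with `df` basis
functions (default 100) and knots at quantiles of the marker positions —
quantile knots make the fit invariant to coordinate rescaling; the exact
knot rule is the `cr()` basis of patsy. Genome binning is half-open
`[start, start + bin)` internally, reported 1-based inclusive, with a
truncated final bin. Breakpoints are binned by the realized painted
junction position (boundaries are intervals; a point assignment is
needed).

Divergence tests use Spearman rank correlation (bin divergence vs. bin
event count) and a Kruskal–Wallis comparison of divergence between bins
with and without events. Correlations of constant vectors are reported as
undefined (`None`) rather than raising. For ≤ 8 bins the Spearman p-value
is computed by exhaustive pairing enumeration; the Kruskal–Wallis
heterogeneity test likewise offers `method="exact"` (full enumeration of
group assignments) because the default chi-square reference is poor at
very small n. Defaults match the standard R behavior (chi-square).

## Locus-level analyses

Allelic states compare variable-site sequences of a replaced locus across
ancestor, donor, and recombinant (gaps are a fifth symbol): recombinant =
donor = ancestor → "K-12 (REL606)"; recombinant = donor ≠ ancestor →
"K-12"; recombinant = ancestor ≠ donor → "REL606"; anything else → "New
allele". The "strong positive selection" flag is consumed as an input
annotation, not derived from a G-score threshold, since no such threshold
is canonically defined. Gene conversion is flagged when a single genome
carries ≥ 3 new mutations in one gene — clustered de novo changes are
far more likely one non-orthologous recombination event than independent
hits; the reported table aggregates lineage, mutation, and position
counts over all genomes. Synonymous recombination:mutation ratios bound
the truth from both sides: the lower bound counts donor-segment
synonymous mutations as genuine mutations, the upper bound excludes them
as recombination artifacts; a zero denominator yields an explicit
"not defined" value rather than an error.

## Continuation dynamics

Frequency trajectories match sites by identity across the two population
samples; a site absent from a sample has frequency 0 (callers report only
variant sites). "Fixed" means frequency ≥ 1 − 10⁻⁹ (float safety only —
the criterion is literal fixation). The LCA haplotype is the intersection
of the two fixed sets with both sequenced clones' call sets. Plasmid
frequency is plasmid coverage / chromosome coverage under one chromosome
per cell and one plasmid per carrier, reported at two significant figures
(the precision coverage summaries support); values above 1 indicate
multi-copy carriage and are returned unclipped. The ratchet model is the
identity map: a neutral allele at frequency *p* fixes with probability
*p* at the next sweep, because a sweep originates on a single random
background.

## Simulator

The generator's defaults are the study conditions it emulates, scaled to
run routinely:

| parameter | default | note |
|---|---|---|
| chromosome | 200 kb circular | scaled from 4.63 Mb; marker density and decay geometry preserved |
| marker density | 8 / kb | K-12-vs-B divergence level |
| donor-specific fraction | 10 % of markers | uniformly assigned to one of 4 donors |
| donors | 4, evenly spaced oriT, alternating orientation | auxotrophy at the donor-specific marker nearest 0.3 genome downstream of its own oriT |
| transfer decay | 10^−2.5 at the 100 kb anchor, 10^−6 at 2.3 Mb | anchors scaled by genome_length / 4.63 Mb; flat below the near anchor; zero beyond 60 % of the chromosome |
| donor : recipient | 4 : 1 | mating attempts per recipient per pulse = 2.5 × ratio |
| treatment | 30 pulses every 33 generations | then 200 generations of conjugation-free continuation |
| population size | 1000, Wright–Fisher | multinomial resampling |
| sweeps | 0.02 per generation | instantaneous: one random cell's haplotype fixes |
| fragmentation | 0 (off) | Poisson breaks per kb; alternate pieces integrated |

Transferred tract lengths are drawn so that P(length ≥ d) equals the
decay law exactly (inverse-CDF sampling of the log-linear survival
function), which makes per-site Monte-Carlo transfer frequencies match
the law with no calibration constant. The anchors constrain only two
points; the log-linear interpolation between them is this package's
choice. The mating intensity (2.5 attempts per donor-excess unit, 10 per
recipient per pulse at the default ratio) is likewise a modeling choice —
the design specifies the cell ratio but not an encounter rate — set so
that the cumulative near-oriT transfer fraction over a 30-pulse treatment
is of order one half, the regime in which replicate populations show
repeated but heterogeneous introgression rather than none or saturation.
Sweeps are instantaneous rather than diffusion-timed: this is exactly the
ratchet-hitchhiking model under test, and a finite-s sweep would only
interpolate between that model and pure drift. A transconjugant that
acquires any of its donor's auxotrophy alleles is removed immediately
(modeled as reversion to the parental cell, keeping N constant).

New mutations and gene-conversion clusters are decorated onto the sampled
clones after the population process (Poisson mean 5 new mutations; one
conversion cluster of 3–6 mutations within 1 kb), at positions disjoint
from marker and recipient-mutation sites. This is sufficient for testing
the detection rules; it does not model mutation accumulation within the
population (population samples therefore contain only marker and
recipient-mutation frequencies).

### What the synthetic tests do and do not show

The simulator reproduces the statistical structure the analyses assume:
dense biallelic markers, distance-decaying unidirectional transfer,
purifying selection at auxotrophy sites, drift, sweeps, and two-timepoint
sampling. Tests against it establish correctness of the set algebra,
painting resolution bounds, profile geometry, and the fixation model. They
do not establish robustness to features of real data the generator omits:
variant-caller error and marginal calls (inputs are treated as ground
truth), mosaic tracts from heteroduplex correction (fragmentation is off
by default and its rate is a free parameter), genomic islands and
structural rearrangements (out of scope), mismatch-repair dependence of
recombination efficiency, and uneven marker density along real genomes.

## Numerical choices

Deterministic output ordering everywhere (site identity sort), explicit
`numpy` Generators threaded through all stochastic code (no global
state), exact rational arithmetic where possible (ratios, bounds), and
spline fitting by `numpy.linalg.lstsq` (bitwise reproducible on one
platform). Degenerate inputs prefer explicit reported values over
exceptions where a value is meaningful (undefined ratios, undefined
correlations); they raise where the input is contractually invalid
(frequencies outside [0, 1], unsorted markers, zero chromosome coverage).

## Problem sizes

Default test and example runs use 50–250 kb chromosomes, 10 populations,
N = 1000, and 10⁴-replicate Monte-Carlo checks; these sizes were chosen so
the full suite completes in seconds while leaving every distributional
check at ≥ 3-sigma resolution.
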