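"""Locus-level analyses of replaced genes in recombinant genomes.

Four questions are answered here for genes whose recipient (evolved)
alleles were replaced during the experiment:

1. *Allelic state*: after replacement, does the gene match the donor, the
   pre-experiment ancestor, both (when donor and ancestor are identical at
   the locus), or neither (a patchwork "new allele")?
2. *Gene conversion*: which genes carry clusters of three or more new
   mutations in a single genome — the signature of a non-orthologous
   recombination event rather than independent point mutations?
3. *Selection on new mutations*: do genes hit by putative gene conversions
   show weaker evidence of positive selection (G score) than genes hit by
   other new nonsynonymous mutations?  (Welch's unequal-variance t-test.)
4. *Recombination vs. mutation*: how many synonymous changes entered each
   genome by recombination versus by new mutation?
"""

from __future__ import annotations

import enum
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


class AllelicState(enum.Enum):
    """Post-replacement relation of a locus to donor and ancestral sequences."""

    K12_ONLY = "K-12"
    K12_EQ_ANC = "K-12 (REL606)"
    ANC_ONLY = "REL606"
    NEW_ALLELE = "New allele"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its positive-selection statistic from the asexual experiment."""

    name: str
    start: int
    coding_length: int
    g_score: float
    strong_selection: bool = False

    def __post_init__(self) -> None:
        if self.coding_length <= 0:
            raise ValueError("coding_length must be positive")
        if self.g_score < 0:
            raise ValueError("g_score must be nonnegative")


@dataclass(frozen=True)
class GeneConversionCall:
    """A gene flagged as a putative gene-conversion target."""

    gene: str
    lineages_mutated: int
    mutation_count: int
    positions_mutated: int


@dataclass(frozen=True)
class SynonymousChangeCounts:
    """Synonymous changes in one genome, split by how and where they arose."""

    recombined_replacements: int
    syn_muts_recipient_segments: int
    syn_muts_donor_segments: int

    def __post_init__(self) -> None:
        if min(
            self.recombined_replacements,
            self.syn_muts_recipient_segments,
            self.syn_muts_donor_segments,
        ) < 0:
            raise ValueError("counts must be nonnegative")


def classify_allelic_state(locus_sequences: Mapping[str, str]) -> AllelicState:
    """Classify one replaced locus from aligned sequences at variable sites.

    ``locus_sequences`` holds equal-length strings for keys ``ancestor``,
    ``donor``, ``recipient`` and ``recombinant`` (variable sites suffice;
    gaps are compared as a fifth symbol).  The recipient sequence carries
    the evolved allele that was replaced; the state depends only on how the
    recombinant relates to donor and ancestor.
    """
    try:
        anc = locus_sequences["ancestor"]
        don = locus_sequences["donor"]
        rec = locus_sequences["recombinant"]
        _ = locus_sequences["recipient"]
    except KeyError as exc:
        raise ValueError(f"missing sequence {exc}") from None
    lengths = {len(v) for v in locus_sequences.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    if rec == don and don == anc:
        return AllelicState.K12_EQ_ANC
    if rec == don:  # and don != anc
        return AllelicState.K12_ONLY
    if rec == anc:  # and anc != don
        return AllelicState.ANC_ONLY
    return AllelicState.NEW_ALLELE


def aggregate_states(
    classified: Iterable[tuple[AllelicState, bool]],
) -> dict[str, int | dict[AllelicState, int]]:
    """Aggregate per-locus states into the summary counts.

    ``classified`` yields ``(state, strong_selection)`` pairs.  A locus
    "reverted to the ancestor" when the recombinant matches the ancestral
    sequence — states ``K12_EQ_ANC`` and ``ANC_ONLY``.
    """
    counts = {state: 0 for state in AllelicState}
    reverted = 0
    reverted_selected = 0
    for state, strong in classified:
        counts[state] += 1
        if state in (AllelicState.K12_EQ_ANC, AllelicState.ANC_ONLY):
            reverted += 1
            if strong:
                reverted_selected += 1
    return {
        "counts": counts,
        "reverted_to_ancestor_count": reverted,
        "reverted_in_selected_genes": reverted_selected,
    }


def detect_gene_conversion(
    new_mutations: Iterable[tuple[str, str, int]],
    threshold: int = 3,
) -> list[GeneConversionCall]:
    """Flag genes with >= ``threshold`` new mutations in a single genome.

    ``new_mutations`` yields ``(gene, genome_id, position)`` triples for
    every new (de novo-labeled) mutation.  The threshold applies within a
    single genome — two mutations in each of two genomes do not qualify —
    but the returned calls aggregate over all genomes: the number of
    distinct mutated lineages, the total mutation count, and the number of
    distinct mutated positions, for each flagged gene.  Output is sorted
    by gene name and invariant to input order.
    """
    per_gene_genome: dict[tuple[str, str], int] = defaultdict(int)
    per_gene: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for gene, genome, pos in new_mutations:
        per_gene_genome[(gene, genome)] += 1
        per_gene[gene].append((genome, pos))
    flagged = sorted(
        {gene for (gene, _), count in per_gene_genome.items() if count >= threshold}
    )
    calls = []
    for gene in flagged:
        entries = per_gene[gene]
        calls.append(
            GeneConversionCall(
                gene=gene,
                lineages_mutated=len({g for g, _ in entries}),
                mutation_count=len(entries),
                positions_mutated=len({p for _, p in entries}),
            )
        )
    return calls


def gscore_welch_test(
    conversion_gene_gscores: Sequence[float],
    other_new_nonsyn_gscores: Sequence[float],
) -> dict[str, float | None]:
    """Welch's two-sided unequal-variance t-test on gene G scores.

    Compares the G scores of genes hit by putative gene conversions with
    those of genes carrying all other new nonsynonymous mutations.  With
    zero variance in both groups the p-value is undefined (None), except
    for the degenerate identical-constant case where p = 1.
    """
    a = np.asarray(conversion_gene_gscores, dtype=float)
    b = np.asarray(other_new_nonsyn_gscores, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    out: dict[str, float | None] = {
        "mean1": float(a.mean()),
        "mean2": float(b.mean()),
    }
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        out["p_two_sided"] = 1.0 if a.mean() == b.mean() else None
        return out
    t, p = stats.ttest_ind(a, b, equal_var=False)
    out["t"] = float(t)
    out["p_two_sided"] = float(p)
    return out


#: sentinel for a ratio with a zero denominator ("not defined")
ND = None


def rec_mut_ratio(counts: SynonymousChangeCounts) -> tuple[float | None, float | None]:
    """Bounds on the ratio of recombined to mutated synonymous changes.

    The lower bound counts synonymous mutations in donor-derived segments
    in the denominator (treating them as genuine new mutations); the upper
    bound excludes them (treating them as recombination artifacts).  A
    bound with a zero denominator is not defined and returned as None.
    When there are no donor-segment mutations the two bounds coincide.
    """
    r = counts.recombined_replacements
    m_rec = counts.syn_muts_recipient_segments
    m_don = counts.syn_muts_donor_segments
    lower = r / (m_rec + m_don) if (m_rec + m_don) > 0 else ND
    upper = r / m_rec if m_rec > 0 else ND
    return lower, upper


def format_ratio(bounds: tuple[float | None, float | None], decimals: int = 1) -> str:
    """Render ratio bounds the way the summary tables print them.

    A single value is shown when the bounds coincide (no donor-segment
    mutations); "ND" marks an undefined bound.
    """

    def fmt(x: float) -> str:
        rounded = round(x, decimals)
        return str(int(rounded)) if rounded == int(rounded) else str(rounded)

    lower, upper = bounds
    if lower is ND and upper is ND:
        return "ND"
    if lower is not ND and upper is not ND:
        if math.isclose(lower, upper):
            return fmt(lower)
        return f"{fmt(lower)}-{fmt(upper)}"
    if lower is not ND:
        return f"{fmt(lower)}-ND"
    return f"ND-{fmt(upper)}"


def assign_to_segments(positions: Sequence[int], segments) -> list[str]:
    """Map each position to the state of the painted segment containing it."""
    out = []
    for pos in positions:
        hit = next((s for s in segments if s.contains(pos)), None)
        if hit is None:
            raise ValueError(f"position {pos} not covered by the painting")
        out.append(hit.state)
    return out
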