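"""Provenance labeling of variant sites in recombinant genomes.

In a conjugation experiment, every genetic difference in a recombinant
genome relative to the shared reference can be explained by one of a small
number of histories: it was already present in the recipient lineage
(vertical inheritance), it came from a donor (horizontal transfer), it
arose de novo, or it disappeared (replaced by donor DNA or deleted).
Classification is pure set algebra over four call-set collections: the
recombinant clone, its parent recipient clone, the union of all donor
genomes, and each donor's private ("donor-specific") marker set.

The nine labels:

==================  =====================================================
label               membership rule
==================  =====================================================
LTEE_MUTATION       in recombinant and recipient, not in donor union
K12_MUTATION        in recombinant and donor union, not in recipient
NEW_MUTATION        in recombinant only
REL606_MARKER       in donor union, not in recipient (and not carried by
                    the recombinant) — a marker differentiating the donor
                    strain background from the reference background
DELETED_MUTATION    in recipient, not in recombinant (replaced or lost);
                    ``in_deleted_region`` records whether the position
                    lies inside a large deletion called in the recombinant
DONOR_SPECIFIC_A-D  the subset of K12_MUTATION sites private to a single
                    donor, attributing the transfer to that donor
==================  =====================================================

Sites identical across recombinant, recipient, and donor union carry no
information and are ignored.  Donor-union markers that fall inside a large
deletion called in the recombinant are also dropped (with a logged count):
a deleted region can support neither donor nor recipient ancestry.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .model import GenomeCallSet, VariantSite

logger = logging.getLogger(__name__)


class ProvenanceLabel(enum.Enum):
    LTEE_MUTATION = "LTEE_MUTATION"
    K12_MUTATION = "K12_MUTATION"
    NEW_MUTATION = "NEW_MUTATION"
    REL606_MARKER = "REL606_MARKER"
    DELETED_MUTATION = "DELETED_MUTATION"
    DONOR_SPECIFIC_A = "DONOR_SPECIFIC_A"
    DONOR_SPECIFIC_B = "DONOR_SPECIFIC_B"
    DONOR_SPECIFIC_C = "DONOR_SPECIFIC_C"
    DONOR_SPECIFIC_D = "DONOR_SPECIFIC_D"


#: The donor-specific labels, in the positional order assigned to sorted donor ids.
DONOR_SPECIFIC_LABELS = (
    ProvenanceLabel.DONOR_SPECIFIC_A,
    ProvenanceLabel.DONOR_SPECIFIC_B,
    ProvenanceLabel.DONOR_SPECIFIC_C,
    ProvenanceLabel.DONOR_SPECIFIC_D,
)


@dataclass(frozen=True)
class LabeledVariant:
    """One site together with its provenance call for one recombinant."""

    site: VariantSite
    label: ProvenanceLabel
    recombinant_id: str
    donor_origin: str | None = None
    in_deleted_region: bool = False

    @property
    def primary_label(self) -> ProvenanceLabel:
        """Collapse donor-specific labels onto K12_MUTATION."""
        if self.label in DONOR_SPECIFIC_LABELS:
            return ProvenanceLabel.K12_MUTATION
        return self.label


def donor_union(donors: list[GenomeCallSet]) -> frozenset[VariantSite]:
    """Union of all sites called in any donor genome."""
    if not donors:
        raise ValueError("at least one donor is required")
    out: set[VariantSite] = set()
    for d in donors:
        out |= d.sites
    return frozenset(out)


def donor_specific(donors: list[GenomeCallSet]) -> dict[str, frozenset[VariantSite]]:
    """Sites private to each donor: present in that donor and absent from all others."""
    if len(donors) < 2:
        raise ValueError("donor specificity requires at least two donors")
    out: dict[str, frozenset[VariantSite]] = {}
    for d in donors:
        others: set[VariantSite] = set()
        for o in donors:
            if o.sample_id != d.sample_id:
                others |= o.sites
        out[d.sample_id] = frozenset(d.sites - others)
    return out


def label_mutations(
    recombinant: GenomeCallSet,
    recipient: GenomeCallSet,
    donors: list[GenomeCallSet],
    ref_length: int,
) -> list[LabeledVariant]:
    """Classify every informative site for one recombinant genome.

    Returns one :class:`LabeledVariant` per site in the universe
    (recombinant ∪ recipient ∪ donor union) that is not identical across
    all three collections and not a donor marker erased by a recombinant
    deletion.  Raises when a recombinant site exceeds ``ref_length``.
    """
    for site in recombinant.sites:
        if site.pos > ref_length:
            raise ValueError(
                f"site {site.chrom}:{site.pos} exceeds reference length {ref_length}"
            )
    union = donor_union(donors)
    specific = donor_specific(donors) if len(donors) >= 2 else {}
    donor_of: dict[VariantSite, str] = {}
    donor_label: dict[str, ProvenanceLabel] = {}
    for idx, donor_id in enumerate(sorted(specific)):
        donor_label[donor_id] = DONOR_SPECIFIC_LABELS[idx % 4]
        for site in specific[donor_id]:
            donor_of[site] = donor_id

    rec, recip = recombinant.sites, recipient.sites
    universe = rec | recip | union
    out: list[LabeledVariant] = []
    dropped_in_deletion = 0
    for site in universe:
        in_rec, in_recip, in_union = site in rec, site in recip, site in union
        if in_rec and in_recip and in_union:
            continue  # uninformative: identical in all three
        if in_rec:
            if in_recip:  # not in union
                label = ProvenanceLabel.LTEE_MUTATION
            elif in_union:
                origin = donor_of.get(site)
                label = donor_label[origin] if origin else ProvenanceLabel.K12_MUTATION
            else:
                label = ProvenanceLabel.NEW_MUTATION
            out.append(
                LabeledVariant(
                    site=site,
                    label=label,
                    recombinant_id=recombinant.sample_id,
                    donor_origin=donor_of.get(site) if in_union else None,
                )
            )
        elif in_recip:
            out.append(
                LabeledVariant(
                    site=site,
                    label=ProvenanceLabel.DELETED_MUTATION,
                    recombinant_id=recombinant.sample_id,
                    in_deleted_region=recombinant.in_deletion(site.pos),
                )
            )
        else:  # in donor union only
            if recombinant.in_deletion(site.pos):
                dropped_in_deletion += 1
                continue
            out.append(
                LabeledVariant(
                    site=site,
                    label=ProvenanceLabel.REL606_MARKER,
                    recombinant_id=recombinant.sample_id,
                    donor_origin=donor_of.get(site),
                )
            )
    if dropped_in_deletion:
        logger.info(
            "%s: dropped %d donor markers inside recombinant deletions",
            recombinant.sample_id,
            dropped_in_deletion,
        )
    return out


def donor_marker_counts(labeled_by_clone: dict[str, list[LabeledVariant]]):
    """Count donor-specific markers per clone per donor.

    Returns a pandas DataFrame indexed by clone id with one column per
    donor id; clones with no donor-specific markers get all-zero rows.
    """
    import pandas as pd

    donors = sorted(
        {
            lv.donor_origin
            for labeled in labeled_by_clone.values()
            for lv in labeled
            if lv.label in DONOR_SPECIFIC_LABELS and lv.donor_origin
        }
    )
    rows = {}
    for clone, labeled in labeled_by_clone.items():
        counts = dict.fromkeys(donors, 0)
        for lv in labeled:
            if lv.label in DONOR_SPECIFIC_LABELS and lv.donor_origin in counts:
                counts[lv.donor_origin] += 1
        rows[clone] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=donors).fillna(0).astype(int)
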