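"""Set-algebra labeling of sites against independent brute-force oracles."""

import numpy as np
import pytest

from introscan.model import GenomeCallSet, Role, VariantKind, VariantSite
from introscan import provenance
from introscan.provenance import ProvenanceLabel

from conftest import snp


def _callset(sample_id, role, positions, deletions=()):
    sites = [snp(p) for p in positions]
    sites += [VariantSite("chr", a, VariantKind.LARGE_DELETION, str(b - a + 1)) for a, b in deletions]
    return GenomeCallSet.from_sites(sample_id, role, sites)


def oracle_label(in_rec, in_recip, in_union):
    """Independent per-site truth table for the primary label (None = ignored)."""
    if in_rec and in_recip and in_union:
        return None
    if in_rec and in_recip:
        return ProvenanceLabel.LTEE_MUTATION
    if in_rec and in_union:
        return ProvenanceLabel.K12_MUTATION
    if in_rec:
        return ProvenanceLabel.NEW_MUTATION
    if in_recip:
        return ProvenanceLabel.DELETED_MUTATION
    return ProvenanceLabel.REL606_MARKER


def random_instance(rng, n_sites=50, p_del=0.0, ref_length=100_000):
    positions = rng.choice(np.arange(1, ref_length + 1), size=n_sites, replace=False)
    membership = rng.random((n_sites, 6)) < rng.uniform(0.2, 0.8)
    recip = _callset("recip", Role.RECIPIENT, positions[membership[:, 0]])
    donors = [
        _callset(f"d{k}", Role.DONOR, positions[membership[:, 1 + k]]) for k in range(4)
    ]
    deletions = []
    if p_del > 0 and rng.random() < p_del:
        a = int(rng.integers(1, ref_length - 5000))
        deletions = [(a, a + 4999)]
    rec = _callset("rec", Role.RECOMBINANT, positions[membership[:, 5]], deletions)
    return positions, membership, recip, donors, rec, deletions


def check_against_oracle(positions, membership, recip, donors, rec, deletions, ref_length=100_000):
    labeled = provenance.label_mutations(rec, recip, donors, ref_length)
    got = {lv.site.pos: lv for lv in labeled if lv.site.kind is VariantKind.SNP}
    union_mask = membership[:, 1:5].any(axis=1)
    for i, pos in enumerate(positions):
        in_rec, in_recip, in_union = membership[i, 5], membership[i, 0], union_mask[i]
        if not (in_rec or in_recip or in_union):
            assert pos not in got
            continue
        expected = oracle_label(in_rec, in_recip, in_union)
        in_del = any(a <= pos <= b for a, b in deletions)
        if expected is None:
            assert pos not in got
        elif expected is ProvenanceLabel.REL606_MARKER and in_del:
            assert pos not in got  # donor marker erased by the deletion
        else:
            assert got[pos].primary_label is expected, pos
            if expected is ProvenanceLabel.DELETED_MUTATION:
                assert got[pos].in_deleted_region == in_del
    return labeled


def test_labels_match_truth_table_on_random_instances(rng):
    for _ in range(50):
        inst = random_instance(rng, n_sites=40, p_del=0.5)
        check_against_oracle(*inst)


def test_partition_property(rng):
    """Every informative site gets exactly one primary label."""
    positions, membership, recip, donors, rec, deletions = random_instance(rng, 200)
    labeled = provenance.label_mutations(rec, recip, donors, 100_000)
    assert len({lv.site for lv in labeled}) == len(labeled)
    union = provenance.donor_union(donors)
    universe = rec.sites | recip.sites | union
    ignored = rec.sites & recip.sites & union
    assert len(labeled) == len(universe) - len(ignored)


def test_recombinant_equal_to_recipient_yields_only_ltee_labels():
    recip = _callset("recip", Role.RECIPIENT, [10, 20, 30])
    rec = _callset("rec", Role.RECOMBINANT, [10, 20, 30])
    donors = [_callset(f"d{k}", Role.DONOR, [1000 + k]) for k in range(2)]
    labeled = provenance.label_mutations(rec, recip, donors, 10_000)
    by_label = {}
    for lv in labeled:
        by_label.setdefault(lv.primary_label, []).append(lv)
    assert len(by_label[ProvenanceLabel.LTEE_MUTATION]) == 3
    assert ProvenanceLabel.K12_MUTATION not in by_label
    assert ProvenanceLabel.NEW_MUTATION not in by_label
    assert ProvenanceLabel.DELETED_MUTATION not in by_label


def test_lost_recipient_site_is_deleted_mutation_outside_deletions():
    recip = _callset("recip", Role.RECIPIENT, [10, 20])
    rec = _callset("rec", Role.RECOMBINANT, [10])
    donors = [_callset(f"d{k}", Role.DONOR, [99]) for k in range(2)]
    labeled = provenance.label_mutations(rec, recip, donors, 1000)
    lost = [lv for lv in labeled if lv.site.pos == 20]
    assert len(lost) == 1
    assert lost[0].label is ProvenanceLabel.DELETED_MUTATION
    assert lost[0].in_deleted_region is False


def test_site_beyond_reference_length_raises():
    rec = _callset("rec", Role.RECOMBINANT, [500])
    recip = _callset("recip", Role.RECIPIENT, [])
    donors = [_callset("d0", Role.DONOR, [1]), _callset("d1", Role.DONOR, [2])]
    with pytest.raises(ValueError, match="exceeds"):
        provenance.label_mutations(rec, recip, donors, 100)


def test_donor_union_matches_brute_force(rng):
    donors = [
        _callset(f"d{k}", Role.DONOR, rng.choice(1000, size=30, replace=False) + 1)
        for k in range(4)
    ]
    union = provenance.donor_union(donors)
    brute = set()
    for d in donors:
        for s in d.sites:
            brute.add(s)
    assert union == brute
    # identity for a single donor, count for disjoint donors
    assert provenance.donor_union(donors[:1]) == donors[0].sites
    d_a = _callset("a", Role.DONOR, [1, 2, 3])
    d_b = _callset("b", Role.DONOR, [4, 5, 6, 7])
    assert len(provenance.donor_union([d_a, d_b])) == 7


def test_donor_specific_matches_per_site_count_filter(rng):
    donors = [
        _callset(f"d{k}", Role.DONOR, rng.choice(200, size=60, replace=False) + 1)
        for k in range(4)
    ]
    specific = provenance.donor_specific(donors)
    all_sites = set().union(*(d.sites for d in donors))
    for site in all_sites:
        holders = [d.sample_id for d in donors if site in d.sites]
        for did in specific:
            assert (site in specific[did]) == (holders == [did])
    shared = _callset("s", Role.DONOR, [42])
    four_same = [_callset(f"e{k}", Role.DONOR, [42]) for k in range(4)]
    assert all(len(s) == 0 for s in provenance.donor_specific(four_same).values())


def test_donor_marker_counts_table(rng):
    positions = np.arange(1, 101)
    donors = [_callset(f"d{k}", Role.DONOR, positions[k * 25 : (k + 1) * 25]) for k in range(4)]
    recip = _callset("recip", Role.RECIPIENT, [])
    # clone carrying only d2-specific DNA
    rec = _callset("cloneA", Role.RECOMBINANT, positions[25:35])
    labeled = provenance.label_mutations(rec, recip, donors, 1000)
    # clone with no donor DNA
    rec0 = _callset("cloneB", Role.RECOMBINANT, [])
    labeled0 = provenance.label_mutations(rec0, recip, donors, 1000)
    table = provenance.donor_marker_counts({"cloneA": labeled, "cloneB": labeled0})
    assert table.loc["cloneA", "d1"] == 10
    assert table.loc["cloneA"].drop("d1").eq(0).all()
    assert table.loc["cloneB"].eq(0).all()
    # donor-specific counts never exceed the clone's total K-12 count
    k12_total = sum(
        1 for lv in labeled if lv.primary_label is ProvenanceLabel.K12_MUTATION
    )
    assert table.loc["cloneA"].sum() <= k12_total
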