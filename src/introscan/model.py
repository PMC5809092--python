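"""Core domain types shared across the pipeline.

Every analysis in this package is phrased in terms of variant calls made
against a single shared reference chromosome (in the motivating experiment,
the *E. coli* B strain REL606).  A :class:`VariantSite` is one such call; a
:class:`GenomeCallSet` is the full set of calls for one sequenced genome or
population sample.  All coordinates are 1-based and inclusive, matching the
convention of both GenomeDiff and VCF.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class VariantKind(str, enum.Enum):
    """The variant classes the pipeline distinguishes."""

    SNP = "SNP"
    SMALL_INDEL = "small_indel"
    IS_INSERTION = "IS_insertion"
    LARGE_DELETION = "large_deletion"


class Role(str, enum.Enum):
    """What a sequenced sample represents in the experimental design."""

    DONOR = "donor"
    RECIPIENT = "recipient"
    RECOMBINANT = "recombinant"
    POPULATION = "population"


@dataclass(frozen=True, order=True)
class VariantSite:
    """A single genetic difference relative to the shared reference.

    The identity of a site — used everywhere set algebra is performed — is
    the tuple ``(chrom, pos, kind, alt)``.  ``alt`` is a descriptor whose
    meaning depends on ``kind``: the new base(s) for a SNP, ``+SEQ`` or
    ``-N`` for a small indel, the mobile-element name for an IS insertion,
    and the deleted span in bp (as digits) for a large deletion.  ``gene``
    and ``syn`` are caller-provided annotations carried through unchanged.
    """

    chrom: str
    pos: int
    kind: VariantKind
    alt: str
    gene: str | None = field(default=None, compare=False)
    syn: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not isinstance(self.kind, VariantKind):
            object.__setattr__(self, "kind", VariantKind(self.kind))
        if self.kind is VariantKind.LARGE_DELETION and self.span < 1:
            raise ValueError("large_deletion must carry a span >= 1")

    @property
    def identity(self) -> tuple[str, int, VariantKind, str]:
        return (self.chrom, self.pos, self.kind, self.alt)

    @property
    def span(self) -> int:
        """Length in bp of the reference interval affected (1 except deletions)."""
        if self.kind is VariantKind.LARGE_DELETION:
            try:
                return int(self.alt)
            except ValueError:
                return 0
        return 1

    @property
    def end(self) -> int:
        """Last affected reference position (inclusive)."""
        return self.pos + self.span - 1


@dataclass
class GenomeCallSet:
    """All variant calls for one sample.

    ``variants`` maps each site to an allele frequency.  For clonal roles
    (donor / recipient / recombinant) the frequency is 1.0 by convention;
    for ``population`` samples it is the metagenomic allele frequency in
    [0, 1].  Duplicate site identities are rejected on construction.
    """

    sample_id: str
    role: Role
    variants: dict[VariantSite, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.role, Role):
            self.role = Role(self.role)
        for site, freq in self.variants.items():
            if not (0.0 <= freq <= 1.0):
                raise ValueError(
                    f"frequency {freq} for {site.identity} outside [0, 1]"
                )

    @classmethod
    def from_sites(
        cls, sample_id: str, role: Role | str, sites, frequency: float = 1.0
    ) -> "GenomeCallSet":
        return cls(sample_id, Role(role), {s: frequency for s in sites})

    @property
    def sites(self) -> frozenset[VariantSite]:
        return frozenset(self.variants)

    def frequency(self, site: VariantSite) -> float:
        """Allele frequency of ``site``; 0.0 when the caller did not report it."""
        return self.variants.get(site, 0.0)

    def add(self, site: VariantSite, frequency: float = 1.0) -> None:
        if site in self.variants:
            raise ValueError(f"duplicate site identity {site.identity}")
        if not (0.0 <= frequency <= 1.0):
            raise ValueError(f"frequency {frequency} outside [0, 1]")
        self.variants[site] = frequency

    def deletion_spans(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) intervals of called large deletions."""
        return sorted(
            (s.pos, s.end)
            for s in self.variants
            if s.kind is VariantKind.LARGE_DELETION
        )

    def in_deletion(self, pos: int) -> bool:
        """True when ``pos`` lies inside any called large deletion."""
        return any(a <= pos <= b for a, b in self.deletion_spans())

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, site: VariantSite) -> bool:
        return site in self.variants


@dataclass(frozen=True)
class CoveragePair:
    """Mean sequencing coverage of the chromosome and of a plasmid replicon."""

    sample_id: str
    chrom_cov: float
    plasmid_cov: float

    def __post_init__(self) -> None:
        if self.chrom_cov < 0 or self.plasmid_cov < 0:
            raise ValueError("coverage values must be nonnegative")


def site_sort_key(site: VariantSite):
    """Deterministic ordering used by every table writer."""
    return (site.chrom, site.pos, site.kind.value, site.alt)
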