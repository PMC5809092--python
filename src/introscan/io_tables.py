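"""Readers and writers for the external table formats.

Three dialects of variant table are supported:

``tsv``
    The package's native flat format: one site per row with columns
    ``chrom, pos, kind, alt, gene, syn, frequency``.
``gd``
    A read/write subset of the GenomeDiff format produced by resequencing
    pipelines.  Only ``SNP``, ``INS``, ``DEL`` and ``MOB`` entries are
    interpreted; every other entry type is skipped and counted.
``vcf``
    A VCF subset (via pysam).  Non-SNP variant classes are written as
    symbolic ALT alleles with the descriptor carried in INFO/ALTDESC, and
    population allele frequencies in INFO/AF.

All positions are 1-based and inclusive in every dialect (identical to the
native VCF/GenomeDiff conventions, so no conversion is applied).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import pysam

from .model import GenomeCallSet, Role, VariantKind, VariantSite, site_sort_key

logger = logging.getLogger(__name__)

#: GD DEL entries at or above this size become large_deletion sites.
LARGE_DELETION_MIN = 50

_EXT_DIALECT = {".gd": "gd", ".vcf": "vcf", ".tsv": "tsv", ".txt": "tsv"}

_TSV_COLUMNS = ["chrom", "pos", "kind", "alt", "gene", "syn", "frequency"]


def sniff_dialect(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext not in _EXT_DIALECT:
        raise ValueError(f"cannot sniff dialect from extension {ext!r}")
    return _EXT_DIALECT[ext]


# ---------------------------------------------------------------------------
# reading


def read_variant_table(
    path: str,
    dialect: str | None = None,
    *,
    sample_id: str | None = None,
    role: Role | str = Role.RECOMBINANT,
    known_contigs: Sequence[str] | None = None,
) -> GenomeCallSet:
    """Read one variant table into a :class:`GenomeCallSet`.

    ``dialect`` is one of ``{"gd", "vcf", "tsv"}`` or None to sniff from the
    file extension.  ``role`` declares what the sample is; for the
    ``population`` role every record must carry an allele frequency.
    Records on contigs not in ``known_contigs`` (when given) are dropped
    with a logged count.
    """
    role = Role(role)
    dialect = dialect or sniff_dialect(path)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    if dialect == "tsv":
        records = _read_tsv(path)
    elif dialect == "gd":
        records = _read_gd(path)
    elif dialect == "vcf":
        records = _read_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    callset = GenomeCallSet(sample_id, role, {})
    dropped = 0
    for site, freq in records:
        if known_contigs is not None and site.chrom not in known_contigs:
            dropped += 1
            continue
        if freq is None:
            if role is Role.POPULATION:
                raise ValueError(
                    f"{path}: population-role record at {site.chrom}:{site.pos} "
                    "has no allele frequency"
                )
            freq = 1.0
        callset.add(site, freq)
    if dropped:
        logger.info("%s: dropped %d records on unknown contigs", path, dropped)
    return callset


def _parse_kind(text: str, lineno: int, path: str) -> VariantKind:
    try:
        return VariantKind(text)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: unknown variant kind {text!r}") from None


def _read_tsv(path: str) -> list[tuple[VariantSite, float | None]]:
    records: list[tuple[VariantSite, float | None]] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:4] != _TSV_COLUMNS[:4]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header starting with "
                        f"{_TSV_COLUMNS[:4]}, got {header[:4]}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                site = VariantSite(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    kind=_parse_kind(row["kind"], lineno, path),
                    alt=row["alt"],
                    gene=row.get("gene") or None,
                    syn=row.get("syn") or None,
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            freq_text = row.get("frequency", "")
            freq = float(freq_text) if freq_text else None
            records.append((site, freq))
    return records


_GD_TYPES = {"SNP", "INS", "DEL", "MOB"}


def _read_gd(path: str) -> list[tuple[VariantSite, float | None]]:
    records: list[tuple[VariantSite, float | None]] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            entry_type = fields[0]
            if entry_type not in _GD_TYPES:
                skipped += 1
                continue
            try:
                chrom, pos = fields[3], int(fields[4])
                extras = {}
                if entry_type == "SNP":
                    kind, alt = VariantKind.SNP, fields[5]
                    tail = fields[6:]
                elif entry_type == "INS":
                    kind, alt = VariantKind.SMALL_INDEL, "+" + fields[5]
                    tail = fields[6:]
                elif entry_type == "DEL":
                    size = int(fields[5])
                    if size >= LARGE_DELETION_MIN:
                        kind, alt = VariantKind.LARGE_DELETION, str(size)
                    else:
                        kind, alt = VariantKind.SMALL_INDEL, f"-{size}"
                    tail = fields[6:]
                else:  # MOB
                    kind, alt = VariantKind.IS_INSERTION, fields[5]
                    tail = fields[8:]
                for item in tail:
                    if "=" in item:
                        key, value = item.split("=", 1)
                        extras[key] = value
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            site = VariantSite(
                chrom=chrom,
                pos=pos,
                kind=kind,
                alt=alt,
                gene=extras.get("gene_name"),
                syn=extras.get("snp_type"),
            )
            freq = float(extras["frequency"]) if "frequency" in extras else None
            records.append((site, freq))
    if skipped:
        logger.info("%s: skipped %d GenomeDiff entries of unsupported types", path, skipped)
    return records


_VCF_SYMBOLIC = {
    VariantKind.SMALL_INDEL: "<INDEL>",
    VariantKind.IS_INSERTION: "<IS>",
    VariantKind.LARGE_DELETION: "<DEL>",
}


def _read_vcf(path: str) -> list[tuple[VariantSite, float | None]]:
    records: list[tuple[VariantSite, float | None]] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            info = rec.info
            kind = VariantKind(info["KIND"])
            alt = info["ALTDESC"]
            if isinstance(alt, tuple):
                alt = alt[0]
            gene = info.get("GENE")
            syn = info.get("SYN")
            site = VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                kind=kind,
                alt=str(alt),
                gene=str(gene) if gene is not None else None,
                syn=str(syn) if syn is not None else None,
            )
            freq = info.get("AF")
            if isinstance(freq, tuple):
                freq = freq[0]
            records.append((site, float(freq) if freq is not None else None))
    return records


# ---------------------------------------------------------------------------
# writing


def write_variant_table(callset: GenomeCallSet, path: str, dialect: str | None = None) -> None:
    """Write a call set in the requested (or sniffed) dialect."""
    dialect = dialect or sniff_dialect(path)
    if dialect == "tsv":
        _write_tsv(callset, path)
    elif dialect == "gd":
        _write_gd(callset, path)
    elif dialect == "vcf":
        _write_vcf(callset, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _ordered(callset: GenomeCallSet):
    return sorted(callset.variants.items(), key=lambda kv: site_sort_key(kv[0]))


def _write_tsv(callset: GenomeCallSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for site, freq in _ordered(callset):
            freq_text = repr(freq) if callset.role is Role.POPULATION else ""
            fh.write(
                "\t".join(
                    [
                        site.chrom,
                        str(site.pos),
                        site.kind.value,
                        site.alt,
                        site.gene or "",
                        site.syn or "",
                        freq_text,
                    ]
                )
                + "\n"
            )


def _write_gd(callset: GenomeCallSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#=GENOME_DIFF\t1.0\n")
        for i, (site, freq) in enumerate(_ordered(callset), start=1):
            extras = []
            if site.gene:
                extras.append(f"gene_name={site.gene}")
            if site.syn:
                extras.append(f"snp_type={site.syn}")
            if callset.role is Role.POPULATION:
                extras.append(f"frequency={freq!r}")
            if site.kind is VariantKind.SNP:
                fields = ["SNP", str(i), ".", site.chrom, str(site.pos), site.alt]
            elif site.kind is VariantKind.SMALL_INDEL:
                if site.alt.startswith("+"):
                    fields = ["INS", str(i), ".", site.chrom, str(site.pos), site.alt[1:]]
                else:
                    fields = ["DEL", str(i), ".", site.chrom, str(site.pos), site.alt.lstrip("-")]
            elif site.kind is VariantKind.LARGE_DELETION:
                fields = ["DEL", str(i), ".", site.chrom, str(site.pos), site.alt]
            else:  # IS insertion
                fields = ["MOB", str(i), ".", site.chrom, str(site.pos), site.alt, "1", "0"]
            fh.write("\t".join(fields + extras) + "\n")


def _write_vcf(callset: GenomeCallSet, path: str) -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "introscan")
    for chrom in sorted({s.chrom for s in callset.variants}):
        header.contigs.add(chrom)
    header.info.add("KIND", 1, "String", "Variant class")
    header.info.add("ALTDESC", 1, "String", "Allele descriptor")
    header.info.add("AF", "A", "Float", "Allele frequency")
    header.info.add("GENE", 1, "String", "Gene annotation")
    header.info.add("SYN", 1, "String", "Coding effect annotation")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for site, freq in _ordered(callset):
            rec = vcf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + site.span,
                alleles=("N", site.alt if site.kind is VariantKind.SNP else _VCF_SYMBOLIC[site.kind]),
            )
            rec.info["KIND"] = site.kind.value
            rec.info["ALTDESC"] = site.alt
            if callset.role is Role.POPULATION:
                rec.info["AF"] = (freq,)
            if site.gene:
                rec.info["GENE"] = site.gene
            if site.syn:
                rec.info["SYN"] = site.syn
            vcf.write(rec)


# ---------------------------------------------------------------------------
# labeled-variant tables

_LABELED_COLUMNS = [
    "chrom",
    "pos",
    "kind",
    "alt",
    "label",
    "in_deleted_region",
    "donor_origin",
    "gene",
    "syn",
]


def write_labeled_table(labeled: Iterable, path: str) -> None:
    """Write provenance-labeled sites as a TSV, ordered by site identity.

    Row order is a pure function of the site identities, so two runs on the
    same input produce byte-identical files.
    """
    rows = sorted(labeled, key=lambda lv: site_sort_key(lv.site))
    with open(path, "w") as fh:
        fh.write("\t".join(_LABELED_COLUMNS) + "\n")
        for lv in rows:
            fh.write(
                "\t".join(
                    [
                        lv.site.chrom,
                        str(lv.site.pos),
                        lv.site.kind.value,
                        lv.site.alt,
                        lv.label.name,
                        "1" if lv.in_deleted_region else "0",
                        lv.donor_origin or "",
                        lv.site.gene or "",
                        lv.site.syn or "",
                    ]
                )
                + "\n"
            )


def read_labeled_table(path: str, recombinant_id: str = ""):
    """Read back a table written by :func:`write_labeled_table`."""
    from .provenance import LabeledVariant, ProvenanceLabel

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LABELED_COLUMNS:
            raise ValueError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            try:
                site = VariantSite(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    kind=VariantKind(row["kind"]),
                    alt=row["alt"],
                    gene=row["gene"] or None,
                    syn=row["syn"] or None,
                )
                label = ProvenanceLabel[row["label"]]
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            out.append(
                LabeledVariant(
                    site=site,
                    label=label,
                    recombinant_id=recombinant_id,
                    donor_origin=row["donor_origin"] or None,
                    in_deleted_region=row["in_deleted_region"] == "1",
                )
            )
    return out


def write_coverage_table(pairs: Sequence, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom_cov\tplasmid_cov\n")
        for p in pairs:
            fh.write(f"{p.sample_id}\t{p.chrom_cov!r}\t{p.plasmid_cov!r}\n")


def read_coverage_table(path: str):
    from .model import CoveragePair

    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sample_id, chrom_cov, plasmid_cov = line.split("\t")
            out.append(CoveragePair(sample_id, float(chrom_cov), float(plasmid_cov)))
    return out
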