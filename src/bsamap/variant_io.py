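"""Readers and writers for the formats the pipeline touches.

VCF (per-bulk allele depths via the AD FORMAT field), GFF3 gene models,
FASTA references, and the TSV tables used between pipeline stages.  All
external coordinates are 1-based inclusive; missing values in TSV are
written as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: The four sequenced DNA pools: maternal parent (mutant), paternal parent
#: (wild type), mutant-phenotype progeny, normal-phenotype progeny.
BULKS = ("MO", "PN", "O", "N")

#: Column order of the per-SNP record table (see :mod:`bsamap.snpindex`).
RECORD_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "index_MO", "index_PN", "index_O", "index_N", "delta",
    "depth_MO", "depth_PN", "depth_O", "depth_N",
]

#: Column order of the sliding-window table.
WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps",
    "mean_index_O", "mean_index_N", "mean_delta",
]

#: Column order of the Monte-Carlo null band table.
BAND_COLUMNS = [
    "chrom", "start", "lower99", "lower95", "upper95", "upper99", "n_sims",
]

_FLOAT_FMT = "%.6f"


class FormatError(ValueError):
    """A file violates the format contract (e.g. missing AD field)."""


@dataclass
class VariantSite:
    """One biallelic SNP with per-bulk (ref_depth, alt_depth) read counts.

    The ALT allele is the maternal (mutant-parent) allele by convention, so
    the SNP-index of a bulk is its ALT-depth fraction.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        for bulk, (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth for bulk {bulk} at {self.chrom}:{self.pos}")

    @property
    def complete(self) -> bool:
        """True when all four bulks carry counts at this site."""
        return all(b in self.counts for b in BULKS)

    def depth(self, bulk: str) -> int:
        r, a = self.counts[bulk]
        return r + a

    def alt_fraction(self, bulk: str) -> float | None:
        """Maternal-allele read fraction for one bulk; None at zero depth."""
        r, a = self.counts[bulk]
        if r + a == 0:
            return None
        return a / (r + a)


@dataclass
class GeneModel:
    """One transcript's coding structure: ordered CDS intervals on a strand.

    ``cds`` holds 1-based inclusive genomic (start, end) intervals sorted by
    genomic coordinate regardless of strand.  A model whose summed CDS length
    is not a multiple of 3 is flagged invalid and refused by the effect
    annotator.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]
    mrna_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds = sorted(self.cds)
        prev_end = 0
        for s, e in self.cds:
            if s > e or s <= prev_end:
                raise ValueError(f"CDS segments of {self.gene_id} overlap or are unordered")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def valid_frame(self) -> bool:
        return self.cds_length % 3 == 0

    def contains(self, pos: int) -> bool:
        """Whether a genomic position falls inside any CDS segment."""
        return any(s <= pos <= e for s, e in self.cds)


def read_bulk_vcf(
    path: str | Path,
    sample_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantSite], int]:
    """Read biallelic SNPs with AD depths for the four bulks.

    Parameters
    ----------
    path
        VCF 4.x file (plain or bgzipped).
    sample_map
        bulk name -> VCF sample column; defaults to identity over
        ``("MO", "PN", "O", "N")``.

    Returns
    -------
    sites, n_skipped
        Sites sorted by (chrom, pos), and the count of multiallelic /
        indel records skipped.

    Raises
    ------
    FormatError
        If the AD FORMAT is absent from a record.
    KeyError
        If a mapped sample name is not in the VCF.
    """
    sample_map = dict(sample_map) if sample_map else {b: b for b in BULKS}
    sites: list[VariantSite] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        for bulk, sample in sample_map.items():
            if sample not in vcf_samples:
                raise KeyError(
                    f"sample {sample!r} (bulk {bulk}) not in VCF samples {vcf_samples}"
                )
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            counts: dict[str, tuple[int, int]] = {}
            for bulk, sample in sample_map.items():
                fmt = rec.samples[sample]
                if "AD" not in fmt or fmt["AD"] is None:
                    raise FormatError(
                        f"record {rec.chrom}:{rec.pos} lacks AD for sample {sample}"
                    )
                ad = fmt["AD"]
                if ad[0] is None:
                    continue  # sample absent at this site
                counts[bulk] = (int(ad[0]), int(ad[1]))
            sites.append(
                VariantSite(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alts[0], counts=counts)
            )
    if n_skipped:
        logger.info("read_bulk_vcf: skipped %d multiallelic/indel records", n_skipped)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites, n_skipped


def write_bulk_vcf(
    sites: Iterable[VariantSite],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write sites as VCF 4.2 with four sample columns carrying AD depths."""
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (REF,ALT)")
    for bulk in BULKS:
        header.add_sample(bulk)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            rec = vf.new_record(contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt))
            for bulk in BULKS:
                if bulk in site.counts:
                    rec.samples[bulk]["AD"] = site.counts[bulk]
            vf.write(rec)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (one per mRNA) from a GFF3 file.

    CDS features are grouped under their mRNA parent; models whose CDS
    length is not divisible by 3 are still returned (callers check
    ``valid_frame`` before annotating — the annotator refuses them).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not cds:
            continue
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                cds=cds,
                mrna_span=(mrna.start, mrna.end),
            )
        )
    # orphan CDS (no mRNA parent) is a format error
    mrna_ids = {m.gene_id for m in models}
    for f in db.features_of_type("CDS"):
        parents = list(db.parents(f, featuretype="mRNA"))
        if not parents:
            raise FormatError(f"CDS at {f.seqid}:{f.start}-{f.end} has no mRNA parent")
    for m in models:
        if not m.valid_frame:
            logger.warning(
                "gene model %s: CDS length %d not divisible by 3; "
                "effect annotation will be refused", m.gene_id, m.cds_length,
            )
    return models


def sites_to_frame(sites: Sequence[VariantSite]) -> pd.DataFrame:
    """Tabulate sites as one row per SNP with per-bulk ref/alt depths."""
    rows = []
    for s in sites:
        row: dict = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
        for b in BULKS:
            r, a = s.counts.get(b, (pd.NA, pd.NA))
            row[f"ref_{b}"], row[f"alt_{b}"] = r, a
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    """Write a pipeline table as TSV: fixed column order, 6-decimal floats, NA missing."""
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_table` (NA parsed back as missing)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
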