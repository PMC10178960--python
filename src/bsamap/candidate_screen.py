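"""Candidate-SNP screening and codon-level effect annotation.

Inside the mapped interval, a candidate causal SNP must look like a fixed
recessive mutation: absent from the paternal bulk (index 0.00), near-fixed
in the maternal bulk (>= 0.85), fixed in the mutant bulk (1.00), at the
heterozygote-carrier frequency in the normal bulk (0.30-0.40), with delta
in 0.60-0.70 — and it must change the encoded protein (missense or a
gained stop codon).

The effect annotator handles single-nucleotide substitutions against
spliced CDS models with the standard genetic code; codons straddling exon
junctions are handled by operating on the spliced CDS sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .variant_io import GeneModel, VariantSite

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class ScreenCriteria:
    """The five index criteria plus the protein-effect requirement.

    Equality criteria ("paternal index is 0.00", "mutant-bulk index is
    1.00") are enforced to an absolute tolerance (exact by default; ~0.02
    is a reasonable relaxation for noisy data).  Range endpoints are
    inclusive.
    """

    pn_index_eq: float = 0.00
    mo_index_min: float = 0.85
    o_index_eq: float = 1.00
    n_index_range: tuple[float, float] = (0.30, 0.40)
    delta_range: tuple[float, float] = (0.60, 0.70)
    required_effects: frozenset[str] = field(
        default_factory=lambda: frozenset({"missense", "stop_gained"})
    )
    eq_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.eq_tolerance < 0:
            raise ValueError("eq_tolerance must be >= 0")
        for lo, hi in (self.n_index_range, self.delta_range):
            if lo > hi:
                raise ValueError("criteria ranges must be well-ordered")


@dataclass
class EffectAnnotation:
    """Codon-level consequence of one SNV against one gene model."""

    gene_id: str
    strand: str
    cds_pos: int | None  # 1-based within the spliced CDS; None if noncoding
    codon_index: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    effect: str  # synonymous | missense | stop_gained | stop_lost | noncoding | splice_adjacent


class ReferenceMismatchError(ValueError):
    """The FASTA base at the site disagrees with the VCF REF allele."""


def apply_screen(records: pd.DataFrame, criteria: ScreenCriteria | None = None) -> pd.DataFrame:
    """Filter a per-SNP record table by the four-bulk index criteria.

    The protein-effect requirement is applied separately after annotation
    (see :func:`screen_candidates`); this function screens on indices only.
    Rows with any missing index fail.
    """
    c = criteria or ScreenCriteria()
    tol = c.eq_tolerance
    m = (
        records["index_PN"].sub(c.pn_index_eq).abs().le(tol)
        & records["index_MO"].ge(c.mo_index_min)
        & records["index_O"].sub(c.o_index_eq).abs().le(tol)
        & records["index_N"].between(*c.n_index_range)
        & records["delta"].between(*c.delta_range)
    )
    return records[m.fillna(False)].reset_index(drop=True)


def _spliced_cds(model: GeneModel, fasta) -> str:
    """Spliced CDS sequence 5'->3' (reverse-complemented for minus strand)."""
    parts = [str(fasta[model.chrom][s - 1 : e]) for s, e in model.cds]
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def _cds_position(model: GeneModel, pos: int) -> int | None:
    """1-based position within the spliced CDS, or None if not in CDS."""
    offset = 0
    for s, e in model.cds:
        if s <= pos <= e:
            genomic_cds_pos = offset + (pos - s) + 1
            if model.strand == "+":
                return genomic_cds_pos
            return model.cds_length - genomic_cds_pos + 1
        offset += e - s + 1
    return None


def _near_splice(model: GeneModel, pos: int, margin: int = 2) -> bool:
    """Within `margin` bp outside a CDS boundary (intronic splice region)."""
    for s, e in model.cds:
        if s - margin <= pos < s or e < pos <= e + margin:
            return True
    return False


def annotate_effect(site: VariantSite, model: GeneModel, fasta) -> EffectAnnotation:
    """Classify one SNV's codon-level effect against one gene model.

    ``fasta`` is a mapping of chromosome name to sequence supporting
    slicing (a ``pyfaidx.Fasta`` or a plain dict of strings).  Raises
    ``ReferenceMismatchError`` if the reference base at the site differs
    from the VCF REF allele, and ``ValueError`` for models whose CDS length
    is not a multiple of 3.
    """
    if site.chrom != model.chrom or not model.contains(site.pos):
        effect = "splice_adjacent" if (
            site.chrom == model.chrom and _near_splice(model, site.pos)
        ) else "noncoding"
        return EffectAnnotation(
            gene_id=model.gene_id, strand=model.strand, cds_pos=None,
            codon_index=None, ref_codon=None, alt_codon=None,
            ref_aa=None, alt_aa=None, effect=effect,
        )
    if not model.valid_frame:
        raise ValueError(
            f"gene model {model.gene_id}: CDS length {model.cds_length} "
            "not divisible by 3; annotation refused"
        )
    ref_base = str(fasta[site.chrom][site.pos - 1 : site.pos]).upper()
    if ref_base != site.ref.upper():
        raise ReferenceMismatchError(
            f"reference base {ref_base} at {site.chrom}:{site.pos} "
            f"differs from VCF REF {site.ref}"
        )

    cds = _spliced_cds(model, fasta)
    cds_pos = _cds_position(model, site.pos)
    assert cds_pos is not None
    ref_allele, alt_allele = site.ref.upper(), site.alt.upper()
    if model.strand == "-":
        ref_allele = ref_allele.translate(_COMPLEMENT)
        alt_allele = alt_allele.translate(_COMPLEMENT)
    if cds[cds_pos - 1] != ref_allele:
        raise ReferenceMismatchError(
            f"spliced CDS base {cds[cds_pos - 1]} at CDS pos {cds_pos} of "
            f"{model.gene_id} differs from strand-adjusted REF {ref_allele}"
        )

    codon_index = (cds_pos - 1) // 3 + 1
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    within = (cds_pos - 1) % 3
    alt_codon = ref_codon[:within] + alt_allele + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gained"
    elif ref_aa == "*":
        effect = "stop_lost"
    else:
        effect = "missense"
    return EffectAnnotation(
        gene_id=model.gene_id, strand=model.strand, cds_pos=cds_pos,
        codon_index=codon_index, ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=ref_aa, alt_aa=alt_aa, effect=effect,
    )


def screen_candidates(
    records: pd.DataFrame,
    sites: list[VariantSite],
    models: list[GeneModel],
    fasta,
    intervals: list[tuple[str, int, int]],
    criteria: ScreenCriteria | None = None,
) -> pd.DataFrame:
    """Full candidate report: index screen + protein-effect filter.

    Records are restricted to the mapped interval(s), screened on the four
    bulk indices, annotated against every overlapping gene model, and kept
    only when the effect is in ``criteria.required_effects``.  One output
    row per passing (SNP, transcript) pair.
    """
    c = criteria or ScreenCriteria()
    site_by_key = {(s.chrom, s.pos): s for s in sites}
    in_interval = pd.Series(False, index=records.index)
    for chrom, start, end in intervals:
        in_interval |= (
            (records["chrom"] == chrom)
            & (records["pos"] >= start)
            & (records["pos"] <= end)
        )
    passing = apply_screen(records[in_interval], c)
    rows = []
    for _, rec in passing.iterrows():
        site = site_by_key[(rec["chrom"], rec["pos"])]
        for model in models:
            if model.chrom != site.chrom or not model.valid_frame:
                continue
            ann = annotate_effect(site, model, fasta)
            if ann.effect not in c.required_effects:
                continue
            rows.append(
                {
                    "chrom": rec["chrom"], "pos": rec["pos"],
                    "index_MO": rec["index_MO"], "index_PN": rec["index_PN"],
                    "index_O": rec["index_O"], "index_N": rec["index_N"],
                    "delta": rec["delta"],
                    "gene_id": ann.gene_id, "cds_pos": ann.cds_pos,
                    "codon_index": ann.codon_index,
                    "ref_aa": ann.ref_aa, "alt_aa": ann.alt_aa,
                    "effect": ann.effect,
                }
            )
    columns = [
        "chrom", "pos", "index_MO", "index_PN", "index_O", "index_N",
        "delta", "gene_id", "cds_pos", "codon_index", "ref_aa", "alt_aa", "effect",
    ]
    return pd.DataFrame(rows, columns=columns)
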