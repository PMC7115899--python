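"""Variant location and coding-consequence classification.

Sex-associated SNPs are placed into one genomic category each — coding
(synonymous / nonsynonymous), splice site, UTR, intron, promoter (2000 bp
upstream to 200 bp downstream of the transcription start, strand-aware) or
intergenic — and nonsynonymous changes are further split into conservative
vs nonconservative according to a four-class amino-acid scheme (nonpolar,
polar, positively charged, negatively charged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import Seq

from .io_formats import GeneModel, VariantRecord

__all__ = [
    "VariantConsequence",
    "DEFAULT_AA_CLASSES",
    "classify_location",
    "coding_consequence",
    "classify_aa_substitution",
    "annotate_variants",
    "consequence_summary",
]

INTERGENIC = "intergenic"
PROMOTER = "promoter"
UTR5 = "utr5"
UTR3 = "utr3"
SPLICE_SITE = "splice_site"
INTRON = "intron"
CODING_SYN = "coding_synonymous"
CODING_NONSYN = "coding_nonsynonymous"

# priority when features of overlapping genes compete (lower wins)
_PRIORITY = {"cds": 0, SPLICE_SITE: 1, UTR5: 2, UTR3: 2, INTRON: 3, PROMOTER: 4}

NONPOLAR = "nonpolar"
POLAR = "polar"
POSITIVE = "positively_charged"
NEGATIVE = "negatively_charged"

DEFAULT_AA_CLASSES: dict[str, str] = {
    **{aa: NONPOLAR for aa in "GAVLIPFMWC"},
    **{aa: POLAR for aa in "STYNQ"},
    **{aa: POSITIVE for aa in "KRH"},
    **{aa: NEGATIVE for aa in "DE"},
}


@dataclass
class VariantConsequence:
    """Location category plus, for coding SNPs, the codon-level consequence."""

    chrom: str
    pos: int
    category: str
    gene_id: str | None = None
    codon_change: str | None = None  # e.g. "CAG>CAC", coding strand
    aa_change: tuple[str, int, str] | None = None  # (ref AA, codon number, alt AA)
    aa_class_change: tuple[str, str] | None = None
    conservative: bool | None = None


def _in_any(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e, *_ in intervals)


def _gene_category(pos: int, gene: GeneModel, promoter_up: int, promoter_down: int):
    """Category of ``pos`` with respect to a single gene, or None."""
    start, end = gene.start, gene.end
    if start <= pos <= end:
        if _in_any(pos, gene.cds):
            return "cds"
        # splice sites: the two intronic bases flanking each exon junction
        for (s1, e1), (s2, _e2) in zip(gene.exons, gene.exons[1:]):
            if e1 < pos < s2 and (pos <= e1 + 2 or pos >= s2 - 2):
                return SPLICE_SITE
        if _in_any(pos, gene.utr5):
            return UTR5
        if _in_any(pos, gene.utr3):
            return UTR3
        if _in_any(pos, gene.exons):
            # exonic but neither CDS nor annotated UTR: side-relative to CDS
            if gene.cds:
                cds_start, cds_end = gene.cds[0][0], gene.cds[-1][1]
                before = pos < cds_start
                return UTR5 if (before == (gene.strand == "+")) else UTR3
            return INTRON  # non-coding gene body
        return INTRON
    # promoter window anchored at the TSS, strand-aware
    if gene.strand == "+":
        if gene.start - promoter_up <= pos <= gene.start + promoter_down:
            return PROMOTER
    else:
        if gene.end - promoter_down <= pos <= gene.end + promoter_up:
            return PROMOTER
    return None


def classify_location(
    variant: VariantRecord,
    gene_models: list[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 200,
) -> tuple[str, str | None]:
    """Assign one location category (and gene) to a variant.

    When overlapping genes disagree, the highest-priority category wins
    (CDS > splice site > UTR > intron > promoter), ties broken by smallest
    gene id.  Positions on chromosomes without gene models are intergenic.
    """
    best: tuple[int, str, str] | None = None  # (priority, gene_id, category)
    for gene in gene_models:
        if gene.chrom != variant.chrom:
            continue
        cat = _gene_category(variant.pos, gene, promoter_up, promoter_down)
        if cat is None:
            continue
        key = (_PRIORITY[cat], gene.gene_id, cat)
        if best is None or key < best:
            best = key
    if best is None:
        return INTERGENIC, None
    return best[2], best[1]


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive sequence fetch from a dict or pyfaidx.Fasta."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start - 1 : end].upper()
    return str(seq[start - 1 : end]).upper()


def coding_consequence(
    variant: VariantRecord, gene: GeneModel, genome: Mapping[str, str]
) -> VariantConsequence:
    """Codon-level consequence of a SNP inside a CDS.

    The reference codon is reconstructed from the spliced CDS (reverse-
    complemented for minus-strand genes, honouring the phase of the first
    coding segment), the alternative base substituted, and both codons
    translated with the standard genetic code.
    """
    if not gene.coding_usable:
        raise ValueError(f"gene {gene.gene_id} flagged unusable for coding consequence")
    if not _in_any(variant.pos, gene.cds):
        raise ValueError(f"{variant.chrom}:{variant.pos} is not inside a CDS of {gene.gene_id}")

    pieces = [_fetch(genome, gene.chrom, s, e) for s, e, _ in gene.cds]
    spliced = "".join(pieces)
    offset = 0
    genomic_index = None
    for (s, e, _), piece in zip(gene.cds, pieces):
        if s <= variant.pos <= e:
            genomic_index = offset + (variant.pos - s)
        offset += len(piece)
    assert genomic_index is not None

    ref_base = spliced[genomic_index]
    if ref_base != variant.ref.upper():
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"FASTA has {ref_base}, variant ref is {variant.ref}"
        )

    if gene.strand == "+":
        coding = spliced
        ci = genomic_index
        alt_base = variant.alt.upper()
        phase = gene.cds[0][2]
    else:
        coding = str(Seq(spliced).reverse_complement())
        ci = len(spliced) - 1 - genomic_index
        alt_base = str(Seq(variant.alt.upper()).complement())
        phase = gene.cds[-1][2]

    ci -= phase
    if ci < 0:
        raise ValueError(f"{variant.chrom}:{variant.pos} falls in a partial leading codon")
    codon_idx = ci // 3
    within = ci % 3
    cstart = phase + 3 * codon_idx
    ref_codon = coding[cstart : cstart + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"incomplete trailing codon at {variant.chrom}:{variant.pos}")
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    synonymous = aa_ref == aa_alt
    cons = VariantConsequence(
        chrom=variant.chrom,
        pos=variant.pos,
        category=CODING_SYN if synonymous else CODING_NONSYN,
        gene_id=gene.gene_id,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=(aa_ref, codon_idx + 1, aa_alt),
    )
    if not synonymous and aa_ref in DEFAULT_AA_CLASSES and aa_alt in DEFAULT_AA_CLASSES:
        conservative, classes = classify_aa_substitution(aa_ref, aa_alt)
        cons.conservative = conservative
        cons.aa_class_change = classes
    return cons


def classify_aa_substitution(
    aa_from: str, aa_to: str, class_map: Mapping[str, str] | None = None
) -> tuple[bool, tuple[str, str]]:
    """Conservative (same physicochemical class) vs nonconservative change."""
    class_map = class_map or DEFAULT_AA_CLASSES
    for aa in (aa_from, aa_to):
        if aa not in class_map:
            raise ValueError(f"nonstandard amino acid {aa!r}")
    pair = (class_map[aa_from], class_map[aa_to])
    return pair[0] == pair[1], pair


def annotate_variants(
    records: list[VariantRecord],
    gene_models: list[GeneModel],
    genome: Mapping[str, str] | None = None,
    promoter_up: int = 2000,
    promoter_down: int = 200,
) -> list[VariantConsequence]:
    """Full per-variant classification: location plus coding consequence.

    CDS variants get codon-level consequences when ``genome`` is supplied
    and the gene's CDS is usable; otherwise they are reported as
    ``coding_unresolved`` (a coding category with no codon fields).
    """
    by_id = {g.gene_id: g for g in gene_models}
    out: list[VariantConsequence] = []
    for rec in records:
        cat, gene_id = classify_location(rec, gene_models, promoter_up, promoter_down)
        if cat == "cds":
            gene = by_id[gene_id]
            if genome is not None and gene.coding_usable:
                out.append(coding_consequence(rec, gene, genome))
                continue
            cat = "coding_unresolved"
        out.append(VariantConsequence(chrom=rec.chrom, pos=rec.pos, category=cat, gene_id=gene_id))
    return out


def consequence_summary(consequences: list[VariantConsequence]) -> dict[str, int]:
    """Tabulate consequences in the standard report layout.

    Category counts sum to the input size; the coding rows additionally
    break down into synonymous/nonsynonymous and conservative/
    nonconservative substitutions.
    """
    counts = {
        INTERGENIC: 0, PROMOTER: 0, UTR5: 0, UTR3: 0, SPLICE_SITE: 0,
        INTRON: 0, "coding": 0, CODING_SYN: 0, CODING_NONSYN: 0,
        "coding_unresolved": 0, "conservative": 0, "nonconservative": 0,
    }
    for c in consequences:
        if c.category in (CODING_SYN, CODING_NONSYN, "coding_unresolved"):
            counts["coding"] += 1
            counts[c.category] += 1
            if c.conservative is True:
                counts["conservative"] += 1
            elif c.conservative is False:
                counts["nonconservative"] += 1
        else:
            counts[c.category] += 1
    counts["total"] = len(consequences)
    return counts
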