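"""Standard-format I/O and the shared data model.

VCF access goes through :mod:`pysam`, GFF3 through :mod:`gffutils` and the
sample sheet through :mod:`pandas`.  All coordinates are 1-based inclusive
(the native VCF/GFF convention) at every module boundary in this package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genotype_model import HET, HOM_ALT, HOM_REF, MISSING

__all__ = [
    "VariantRecord",
    "SampleInfo",
    "GeneModel",
    "VcfFormatError",
    "read_vcf",
    "write_vcf",
    "read_gff",
    "read_sample_sheet",
    "genotype_matrix",
    "depth_matrix",
]

logger = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"

_SEX_TOKENS = {
    "f": FEMALE, "female": FEMALE, "fem": FEMALE,
    "m": MALE, "male": MALE,
}


class VcfFormatError(ValueError):
    """Raised for malformed VCF input; names the offending line if known."""


@dataclass
class VariantRecord:
    """One biallelic VCF site with per-sample genotype evidence.

    ``genotypes`` holds alt-allele dosage codes (0 hom_ref, 1 het,
    2 hom_alt, -1 missing); ``depths`` the per-sample read depth (DP; 0 for
    missing genotypes, -1 when the file carries no depth information); and
    ``allele_depths`` (ref_reads, alt_reads) pairs (AD; -1,-1 when absent).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotypes: np.ndarray  # int8 (n_samples,)
    depths: np.ndarray  # int32 (n_samples,)
    allele_depths: np.ndarray  # int32 (n_samples, 2)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.shape[0])


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str  # "female" | "male"
    stratum: str

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"unknown sex {self.sex!r} for sample {self.sample_id}")


@dataclass
class GeneModel:
    """One gene with its (first) transcript structure, 1-based inclusive.

    ``cds`` intervals carry the reading-frame phase of their first base.
    ``coding_usable`` is cleared when the summed CDS length is not a multiple
    of three, in which case the gene is excluded from coding-consequence
    calls but still usable for location classification.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    coding_usable: bool = True

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)

    @property
    def start(self) -> int:
        return self.exons[0][0] if self.exons else self.cds[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1] if self.exons else self.cds[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _gt_code(gt_tuple, focal_alt: int) -> int:
    """Map a pysam GT allele-index tuple to a dosage code for one alt allele."""
    if gt_tuple is None or any(a is None for a in gt_tuple):
        return MISSING
    # alleles other than ref and the focal alt make the call uninterpretable
    # for this biallelic split -> missing
    if any(a not in (0, focal_alt) for a in gt_tuple):
        return MISSING
    return sum(1 for a in gt_tuple if a == focal_alt)


def read_vcf(path, split_multiallelic: bool = True):
    """Read a VCF 4.x into (records, sample_ids).

    Multiallelic lines are split into one biallelic record per alternative
    allele (genotypes carrying a different alt become missing for that
    split); with ``split_multiallelic=False`` such lines are skipped.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except Exception as exc:  # pysam raises various types on bad headers
        raise VcfFormatError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.header.samples)
    records: list[VariantRecord] = []
    n = len(samples)
    try:
        for line_no, rec in enumerate(vcf, start=1):
            if rec.alts is None:
                continue
            if len(rec.alts) > 1 and not split_multiallelic:
                continue
            if len(rec.samples) != n:
                raise VcfFormatError(
                    f"{path}: data line {line_no} has {len(rec.samples)} "
                    f"sample columns, header declares {n}"
                )
            for alt_idx, alt in enumerate(rec.alts, start=1):
                genotypes = np.empty(n, dtype=np.int8)
                depths = np.empty(n, dtype=np.int32)
                ad = np.full((n, 2), -1, dtype=np.int32)
                for i, sample in enumerate(samples):
                    call = rec.samples[sample]
                    code = _gt_code(call.get("GT"), alt_idx)
                    genotypes[i] = code
                    dp = call.get("DP")
                    sample_ad = call.get("AD")
                    if sample_ad is not None and sample_ad[0] is not None:
                        ad[i, 0] = sample_ad[0]
                        ad[i, 1] = sample_ad[alt_idx]
                    if dp is not None:
                        depths[i] = dp
                    elif ad[i, 0] >= 0:
                        depths[i] = ad[i, 0] + ad[i, 1]
                    else:
                        depths[i] = 0 if code == MISSING else -1
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else float("nan"),
                        genotypes=genotypes,
                        depths=depths,
                        allele_depths=ad,
                    )
                )
    except VcfFormatError:
        raise
    except Exception as exc:
        raise VcfFormatError(f"{path}: malformed VCF body ({exc})") from exc
    return records, samples


_GT_FIELD = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(records: list[VariantRecord], samples: list[str], path) -> None:
    """Write records as a plain-text VCF 4.2 with GT:DP:AD fields.

    Records must be coordinate-sorted (chromosomes contiguous, positions
    non-decreasing within each chromosome); the output re-reads losslessly
    for every field the data model stores.
    """
    seen: dict[str, int] = {}
    prev_chrom, prev_pos = None, 0
    for rec in records:
        if rec.chrom != prev_chrom:
            if rec.chrom in seen:
                raise ValueError(f"records not sorted: chromosome {rec.chrom} not contiguous")
            seen[rec.chrom] = 1
            prev_chrom, prev_pos = rec.chrom, rec.pos
        elif rec.pos < prev_pos:
            raise ValueError(f"records not sorted at {rec.chrom}:{rec.pos}")
        prev_pos = rec.pos

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic read depths">'
    )
    for chrom in seen:
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vr = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,  # pysam uses 0-based start internally
                alleles=(rec.ref, rec.alt),
            )
            vr.qual = rec.qual
            for i, s in enumerate(samples):
                call = vr.samples[s]
                call["GT"] = _GT_FIELD[int(rec.genotypes[i])]
                call.phased = False
                if rec.depths[i] >= 0:
                    call["DP"] = int(rec.depths[i])
                if rec.allele_depths[i, 0] >= 0:
                    call["AD"] = (int(rec.allele_depths[i, 0]), int(rec.allele_depths[i, 1]))
            out.write(vr)


def genotype_matrix(records: list[VariantRecord]) -> np.ndarray:
    """Stack per-record genotype codes into a (n_sites, n_samples) int8 array."""
    if not records:
        return np.empty((0, 0), dtype=np.int8)
    return np.vstack([r.genotypes for r in records])


def depth_matrix(records: list[VariantRecord]) -> np.ndarray:
    if not records:
        return np.empty((0, 0), dtype=np.int32)
    return np.vstack([r.depths for r in records])


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path) -> list[GeneModel]:
    """Parse GFF3 gene models (gene -> mRNA -> exon/CDS/UTR).

    Coordinates stay 1-based inclusive.  For genes with several transcripts
    the first mRNA (by id) is used.  Genes whose CDS length is not a
    multiple of three are flagged ``coding_usable=False`` with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = sorted(
            db.children(gene, featuretype=("mRNA", "transcript")), key=lambda f: f.id
        )
        parent = transcripts[0] if transcripts else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = []
        for f in db.children(parent, featuretype="CDS"):
            phase = int(f.frame) if f.frame not in (None, ".") else 0
            cds.append((f.start, f.end, phase))
        utr5 = [
            (f.start, f.end)
            for f in db.children(parent, featuretype=("five_prime_UTR", "5UTR"))
        ]
        utr3 = [
            (f.start, f.end)
            for f in db.children(parent, featuretype=("three_prime_UTR", "3UTR"))
        ]
        if not exons:
            exons = [(gene.start, gene.end)]
        model = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            exons=exons, cds=cds, utr5=utr5, utr3=utr3,
        )
        if cds and model.cds_length % 3 != 0:
            warnings.warn(
                f"gene {gene.id}: CDS length {model.cds_length} not divisible by 3; "
                "excluded from coding-consequence calls"
            )
            model.coding_usable = False
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleInfo]:
    """Read a tab-separated sheet with columns sample_id, sex, stratum."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "stratum"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {sorted(missing_cols)}")
    infos: list[SampleInfo] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        token = str(row.sex).strip().lower()
        if token not in _SEX_TOKENS:
            raise ValueError(f"unknown sex token {row.sex!r} for sample {row.sample_id}")
        if row.sample_id in seen:
            raise ValueError(f"duplicate sample id {row.sample_id!r}")
        seen.add(row.sample_id)
        infos.append(SampleInfo(row.sample_id, _SEX_TOKENS[token], str(row.stratum)))
    by_sex = pd.Series([s.sex for s in infos]).value_counts().to_dict()
    by_stratum = pd.Series([s.stratum for s in infos]).value_counts().to_dict()
    logger.info("sample sheet: %d samples, by sex %s, by stratum %s",
                len(infos), by_sex, by_stratum)
    return infos


def write_sample_sheet(samples: list[SampleInfo], path) -> None:
    df = pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples],
         "sex": [s.sex for s in samples],
         "stratum": [s.stratum for s in samples]}
    )
    df.to_csv(path, sep="\t", index=False)
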