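"""Readers and writers for every external format the pipeline touches.

All in-memory coordinates are 0-based, half-open.  Conversion to the 1-based
conventions of VCF, gene-model TSVs and site tables happens here and only
here; BED is already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .errors import FormatError, ValidationError

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class ReferenceSequence:
    """One contig of the reference genome, uppercase over {A,C,G,T,N}."""

    contig_name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValidationError(f"reference contig {self.contig_name!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    def base_at(self, position: int) -> str:
        return self.bases[position]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with optional strand and label."""

    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene as interval lists per feature class; UTRs lie inside exons."""

    gene_id: str
    gene_type: str  # "protein_coding" or "noncoding_or_RNA"
    exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(iv.start for iv in self.exons + self.introns)

    @property
    def end(self) -> int:
        return max(iv.end for iv in self.exons + self.introns)

    @property
    def contig(self) -> str:
        return (self.exons + self.introns)[0].contig


@dataclass
class PileupColumn:
    """Per-base counts at one covered reference position (0-based)."""

    contig: str
    position: int
    ref_base: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for base, n in self.counts.items():
            if n < 0:
                raise ValidationError(
                    f"negative count {n} for base {base} at "
                    f"{self.contig}:{self.position}"
                )

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def count(self, base: str) -> int:
        return self.counts.get(base, 0)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Parse a FASTA file into uppercased reference sequences."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed record
        raise FormatError(f"malformed FASTA in {path}: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"FASTA record with empty header in {path}")
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ReferenceSequence(contig_name=rec.id, bases=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Iterable[ReferenceSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.contig_name}\n")
            for i in range(0, len(seq.bases), width):
                fh.write(seq.bases[i:i + width] + "\n")


def reference_by_contig(
    sequences: Iterable[ReferenceSequence],
) -> dict[str, ReferenceSequence]:
    return {s.contig_name: s for s in sequences}


# ---------------------------------------------------------------------------
# VCF (known SNP positions only; CHROM/POS are all we consume)


def read_vcf_positions(path: str | Path) -> set[tuple[str, int]]:
    """Return the set of (contig, 0-based position) for every VCF data row."""
    positions: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: too few VCF columns")
            try:
                pos = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer POS {fields[1]!r}"
                ) from None
            positions.add((fields[0], pos - 1))
    return positions


def write_vcf(
    rows: Iterable[tuple[str, int, str, str]], path: str | Path
) -> None:
    """Write minimal VCF rows given (contig, 0-based pos, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt in rows:
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# BED (Alu intervals)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3+ file; BED is already 0-based half-open."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            intervals.append(
                GenomicInterval(fields[0], start, end, strand=strand, label=label)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (6+1 column TSV; 1-based inclusive coordinates in the file)

_GENE_FEATURES = {"exon", "intron", "5utr", "3utr"}
_GENE_TYPES = {"protein_coding", "noncoding_or_RNA"}


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the tabular gene-model format.

    Columns: gene_id, gene_type, feature in {exon,intron,5utr,3utr},
    contig, start (1-based), end (inclusive), strand.  Rows for one gene
    are grouped by gene_id; order of first appearance is preserved.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            gene_id, gene_type, feature, contig, start_s, end_s, strand = fields[:7]
            if gene_type not in _GENE_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown gene_type {gene_type!r}")
            if feature not in _GENE_FEATURES:
                raise FormatError(f"{path}:{lineno}: unknown feature {feature!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            iv = GenomicInterval(contig, start - 1, end, strand=strand)
            gene = genes.setdefault(gene_id, GeneModel(gene_id, gene_type))
            {"exon": gene.exons, "intron": gene.introns,
             "5utr": gene.utr5, "3utr": gene.utr3}[feature].append(iv)
    return list(genes.values())


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tgene_type\tfeature\tcontig\tstart\tend\tstrand\n")
        for gene in genes:
            for feature, ivs in (
                ("exon", gene.exons), ("intron", gene.introns),
                ("5utr", gene.utr5), ("3utr", gene.utr3),
            ):
                for iv in ivs:
                    fh.write(
                        f"{gene.gene_id}\t{gene.gene_type}\t{feature}\t"
                        f"{iv.contig}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\n"
                    )


# ---------------------------------------------------------------------------
# Alignments / pileup


@dataclass(frozen=True)
class QualityParams:
    """Quality gates for the SAM path; the pileup-TSV path ignores them."""

    min_base_quality: int = 20
    min_mapping_quality: int = 20


def pileup_from_sam(
    path: str | Path,
    reference: dict[str, ReferenceSequence],
    quality_params: QualityParams | None = None,
) -> Iterator[PileupColumn]:
    """Stream per-position base counts from a SAM file.

    Reads below the mapping-quality gate are skipped entirely; aligned bases
    below the base-quality gate are skipped individually.  Deletions and
    reference skips contribute nothing to the columns they span.  Unmapped
    reads are ignored.
    """
    qp = quality_params or QualityParams()
    counts: dict[tuple[str, int], dict[str, int]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.query_sequence is None:
                continue
            contig = read.reference_name
            if contig not in reference:
                raise FormatError(
                    f"alignment references unknown contig {contig!r}"
                )
            if read.mapping_quality < qp.min_mapping_quality:
                continue
            quals = read.query_qualities  # None when SAM QUAL column is '*'
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < qp.min_base_quality:
                    continue
                base = seq[qpos].upper()
                if base not in "ACGT":
                    continue
                col = counts.setdefault((contig, rpos), {})
                col[base] = col.get(base, 0) + 1
    for (contig, pos), col in sorted(counts.items()):
        yield PileupColumn(
            contig=contig,
            position=pos,
            ref_base=reference[contig].base_at(pos),
            counts=col,
        )


def read_pileup_tsv(
    path: str | Path, reference: dict[str, ReferenceSequence] | None = None
) -> Iterator[PileupColumn]:
    """Stream pileup columns from a TSV of contig, pos(1-based), ref, A,C,G,T."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 pileup columns")
            contig, pos_s, ref_base = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s) - 1
                base_counts = [int(x) for x in fields[3:7]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer field") from None
            if any(n < 0 for n in base_counts):
                raise FormatError(f"{path}:{lineno}: negative count")
            if reference is not None and contig not in reference:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            yield PileupColumn(
                contig=contig,
                position=pos,
                ref_base=ref_base,
                counts=dict(zip("ACGT", base_counts)),
            )


def write_pileup_tsv(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tref\tA\tC\tG\tT\n")
        for col in columns:
            fh.write(
                f"{col.contig}\t{col.position + 1}\t{col.ref_base}\t"
                f"{col.count('A')}\t{col.count('C')}\t{col.count('G')}\t"
                f"{col.count('T')}\n"
            )


def read_alignments_or_pileup(
    path: str | Path,
    reference: dict[str, ReferenceSequence],
    quality_params: QualityParams | None = None,
) -> Iterator[PileupColumn]:
    """Dispatch on extension: .sam goes through the alignment reader,
    anything else is treated as a pileup TSV."""
    if str(path).endswith(".sam"):
        return pileup_from_sam(path, reference, quality_params)
    return read_pileup_tsv(path, reference)


# ---------------------------------------------------------------------------
# Site tables (1-based positions in the file, documented in the header)

SITE_TABLE_COLUMNS = [
    "contig", "position", "edit_type", "strand", "edits", "reads",
    "ratio", "snp_filtered", "region_class", "in_alu",
]


def write_site_table(sites, path: str | Path) -> None:
    """Write EditSite records as TSV; positions are converted to 1-based."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SITE_TABLE_COLUMNS) + "\n")
        for s in sites:
            in_alu = "." if s.in_alu is None else str(int(s.in_alu))
            region = s.region_class or "."
            fh.write(
                f"{s.contig}\t{s.position + 1}\t{s.edit_type}\t{s.strand}\t"
                f"{s.edit_count}\t{s.total_reads}\t{s.edit_ratio:.10g}\t"
                f"{int(s.snp_filtered)}\t{region}\t{in_alu}\n"
            )


def read_site_table(path: str | Path):
    """Read a site-table TSV back into EditSite records (exact round-trip)."""
    from .edit_detection import EditSite  # local import: avoid cycle

    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(SITE_TABLE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            (contig, pos_s, edit_type, strand, edits_s, reads_s, ratio_s,
             snp_s, region, in_alu_s) = fields
            try:
                position = int(pos_s) - 1
                edits, reads = int(edits_s), int(reads_s)
                ratio = float(ratio_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from None
            if not (0.0 <= ratio <= 1.0) or math.isnan(ratio):
                raise FormatError(
                    f"{path}:{lineno}: ratio {ratio_s} outside [0, 1]"
                )
            sites.append(EditSite(
                contig=contig,
                position=position,
                edit_type=edit_type,
                strand=strand,
                edit_count=edits,
                total_reads=reads,
                snp_filtered=bool(int(snp_s)),
                region_class=None if region == "." else region,
                in_alu=None if in_alu_s == "." else bool(int(in_alu_s)),
            ))
    return sites


# ---------------------------------------------------------------------------
# Cohort CSV

COHORT_COLUMNS = [
    "patient_id", "phase", "survival_weeks", "event", "adar_expr",
    "gzma_expr", "prf1_expr", "mutation_load", "neoantigen_load",
    "neopeptide_load",
]

_REQUIRED_COHORT = {"patient_id", "phase", "survival_weeks", "event"}


def _opt_float(value: str, what: str, lineno: int, path) -> float | None:
    if value is None or value.strip() in {"", "NA", "nan", "."}:
        return None
    try:
        return float(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric {what} {value!r}") from None


def read_cohort_csv(path: str | Path):
    """Read the per-sample cohort table into CohortRecord objects.

    Survival time and event flag are required; covariates may be missing and
    come back as None.  An AEI column is optional (it is usually joined later
    from the editing-index stage).
    """
    from .cohort_analysis import CohortRecord  # local import: avoid cycle

    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not _REQUIRED_COHORT <= set(reader.fieldnames):
            missing = _REQUIRED_COHORT - set(reader.fieldnames or [])
            raise FormatError(f"{path}: missing cohort columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            phase = row["phase"].strip()
            if phase not in {"pre", "on"}:
                raise FormatError(f"{path}:{lineno}: phase must be pre/on, got {phase!r}")
            try:
                survival = float(row["survival_weeks"])
                event = int(row["event"])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad survival/event") from None
            if survival < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative survival time {survival}"
                )
            if event not in (0, 1):
                raise ValidationError(f"{path}:{lineno}: event must be 0/1")
            records.append(CohortRecord(
                patient_id=row["patient_id"].strip(),
                phase=phase,
                aei=_opt_float(row.get("aei"), "aei", lineno, path),
                survival_weeks=survival,
                event=event,
                adar_expr=_opt_float(row.get("adar_expr"), "adar_expr", lineno, path),
                gzma_expr=_opt_float(row.get("gzma_expr"), "gzma_expr", lineno, path),
                prf1_expr=_opt_float(row.get("prf1_expr"), "prf1_expr", lineno, path),
                mutation_load=_opt_float(row.get("mutation_load"), "mutation_load", lineno, path),
                neoantigen_load=_opt_float(row.get("neoantigen_load"), "neoantigen_load", lineno, path),
                neopeptide_load=_opt_float(row.get("neopeptide_load"), "neopeptide_load", lineno, path),
            ))
    return records


def group_cohort_by_patient(records) -> dict[str, dict[str, object]]:
    """Map patient_id -> {phase: record}; paired retrieval helper."""
    grouped: dict[str, dict[str, object]] = {}
    for rec in records:
        grouped.setdefault(rec.patient_id, {})[rec.phase] = rec
    return grouped
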