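"""Seeded synthetic-data generation for the whole pipeline.

Everything the pipeline consumes can be generated here from an explicit
:class:`SimulationConfig`: a random reference contig with embedded Alu
intervals and gene models, known SNPs, per-sample pileups with known
per-site editing rates, and a patient cohort whose hazard of death
increases with true AEI while ADAR expression tracks it positively.
Ground truth is returned alongside every artefact so tests can compare
against it.  All randomness flows through ``numpy.random.default_rng``
seeded from the config, so every output is reproducible bit-for-bit.

Simulation operates at pileup granularity; a minimal read/SAM writer is
provided to exercise the alignment reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SizingError, ValidationError
from .io_formats import (
    GeneModel, GenomicInterval, PileupColumn, ReferenceSequence,
    write_bed, write_fasta, write_gene_models, write_pileup_tsv, write_vcf,
)

_BASES = np.array(list("ACGT"))
_EDIT_ALT = {"A": "G", "T": "C"}


@dataclass
class SimulationConfig:
    """Every knob of the generator, with calibrated defaults.

    ``aei_scale_target`` and ``cohort_n`` default to the published cohort
    scale (mean 48, SD 27, N=23).  ``hazard_slope`` is calibrated so the
    population Spearman correlation between AEI and death time is ~ -0.5.
    """

    seed: int = 0
    contig_name: str = "chrS"
    contig_length: int = 8000
    n_genes: int = 4
    n_alu: int = 8
    alu_length_min: int = 150
    alu_length_max: int = 320
    n_edit_sites: int = 200
    edit_rate_alpha: float = 2.0
    edit_rate_beta: float = 2.0
    fraction_of_edit_sites_in_alu: float = 0.8
    mean_depth: float = 50.0
    depth_dispersion: float = 10.0
    base_error_rate: float = 0.001
    n_snps: int = 30
    snp_het_fraction: float = 1.0
    n_samples: int = 2
    cohort_n: int = 23
    aei_mean_target: float = 48.0
    aei_sd_target: float = 27.0
    hazard_baseline: float = 0.01
    hazard_slope: float = 0.75
    on_therapy_aei_shift: float = 11.0
    on_therapy_aei_noise_sd: float = 15.0
    adar_intercept: float = 40.0
    adar_slope: float = 1.0
    adar_noise_sd: float = 15.0
    covariate_log_mean: float = 5.5
    covariate_log_sd: float = 1.0
    censor_time: float | None = None

    def validate(self) -> None:
        if self.contig_length <= 0 or self.n_edit_sites < 0 or self.n_snps < 0:
            raise ValidationError("sizes must be nonnegative (contig positive)")
        for name in ("base_error_rate", "fraction_of_edit_sites_in_alu",
                     "snp_het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.edit_rate_alpha <= 0 or self.edit_rate_beta <= 0:
            raise ValidationError("Beta parameters must be positive")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValidationError("depth parameters must be positive")
        if self.hazard_baseline <= 0:
            raise ValidationError("hazard_baseline must be positive")
        if self.cohort_n < 2:
            raise ValidationError("cohort_n must be >= 2")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class TruthSite:
    contig: str
    position: int  # 0-based
    edit_type: str  # AG or TC
    strand: str
    rate: float
    in_alu: bool


@dataclass(frozen=True)
class TruthSnp:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    alt_fraction: float  # 0.5 heterozygous, 1.0 homozygous alt


@dataclass
class SimulationTruth:
    """Container tying together every generated artefact and its truth."""

    config: SimulationConfig
    reference: ReferenceSequence
    alu_intervals: list[GenomicInterval]
    gene_models: list[GeneModel]
    snps: list[TruthSnp]
    sites: list[TruthSite] = field(default_factory=list)
    sample_rate_scale: dict[str, float] = field(default_factory=dict)
    cohort: pd.DataFrame | None = None
    cohort_truth: pd.DataFrame | None = None

    @property
    def snp_positions(self) -> set[tuple[str, int]]:
        return {(s.contig, s.position) for s in self.snps}

    def true_aei(self, rate_scale: float = 1.0) -> float:
        return float(sum(min(s.rate * rate_scale, 1.0) for s in self.sites))


# ---------------------------------------------------------------------------
# Reference, features, SNPs


def _place_nonoverlapping(
    rng: np.random.Generator, contig_length: int, lengths: Sequence[int],
    occupied: list[tuple[int, int]] | None = None, max_tries: int = 2000,
) -> list[tuple[int, int]]:
    """Place intervals of the given lengths without mutual overlap."""
    placed: list[tuple[int, int]] = list(occupied or [])
    result = []
    for length in lengths:
        if length > contig_length:
            raise SizingError(
                f"feature length {length} exceeds contig length {contig_length}; "
                "increase contig_length"
            )
        for _ in range(max_tries):
            start = int(rng.integers(0, contig_length - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in placed):
                placed.append((start, end))
                result.append((start, end))
                break
        else:
            raise SizingError(
                "could not place all requested features; reduce counts or "
                "increase contig_length"
            )
    return result


def _build_gene(gene_id: str, gene_type: str, contig: str,
                start: int, end: int, strand: str) -> GeneModel:
    """Three exons with two introns; protein-coding genes get terminal UTRs."""
    span = end - start
    exon_len = max(span // 9, 10)
    intron_len = (span - 3 * exon_len) // 2
    e1 = GenomicInterval(contig, start, start + exon_len, strand)
    i1 = GenomicInterval(contig, e1.end, e1.end + intron_len, strand)
    e2 = GenomicInterval(contig, i1.end, i1.end + exon_len, strand)
    i2 = GenomicInterval(contig, e2.end, e2.end + intron_len, strand)
    e3 = GenomicInterval(contig, i2.end, end, strand)
    gene = GeneModel(gene_id, gene_type, exons=[e1, e2, e3], introns=[i1, i2])
    if gene_type == "protein_coding":
        utr_len = max(exon_len // 3, 5)
        gene.utr5 = [GenomicInterval(contig, e1.start, e1.start + utr_len, strand)]
        gene.utr3 = [GenomicInterval(contig, e3.end - utr_len, e3.end, strand)]
    return gene


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceSequence, list[GenomicInterval], list[GeneModel], list[TruthSnp]]:
    """Random contig with embedded Alu intervals, gene models, and SNPs.

    Alu intervals do not overlap each other (they may fall inside genes,
    as in real genomes); genes do not overlap each other.  SNP positions
    are chosen at A/T bases with an edit-mimicking alternate allele, and
    later site placement avoids them, so SNPs and true edit sites are
    always disjoint.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bases = rng.choice(_BASES, size=config.contig_length)
    reference = ReferenceSequence(config.contig_name, "".join(bases))

    gene_min = max(config.contig_length // (config.n_genes * 3), 120) if config.n_genes else 0
    gene_lengths = [int(rng.integers(gene_min, gene_min * 2 + 1))
                    for _ in range(config.n_genes)]
    gene_spans = _place_nonoverlapping(rng, config.contig_length, gene_lengths)
    gene_models = []
    for i, (start, end) in enumerate(sorted(gene_spans)):
        gene_type = "protein_coding" if rng.random() < 0.7 else "noncoding_or_RNA"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_models.append(_build_gene(f"GENE{i + 1:03d}", gene_type,
                                       config.contig_name, start, end, strand))

    alu_lengths = [int(rng.integers(config.alu_length_min, config.alu_length_max + 1))
                   for _ in range(config.n_alu)]
    alu_spans = _place_nonoverlapping(rng, config.contig_length, alu_lengths)
    families = ["AluY", "AluJb", "AluSx"]
    alu_intervals = [
        GenomicInterval(config.contig_name, s, e,
                        strand="+" if rng.random() < 0.5 else "-",
                        label=families[i % len(families)])
        for i, (s, e) in enumerate(sorted(alu_spans))
    ]

    at_positions = np.flatnonzero(np.isin(bases, ["A", "T"]))
    if len(at_positions) < config.n_snps:
        raise SizingError("not enough A/T positions for the requested SNPs")
    snp_pos = rng.choice(at_positions, size=config.n_snps, replace=False)
    snps = []
    for pos in sorted(int(p) for p in snp_pos):
        ref_base = bases[pos]
        het = rng.random() < config.snp_het_fraction
        snps.append(TruthSnp(config.contig_name, pos, str(ref_base),
                             _EDIT_ALT[str(ref_base)],
                             alt_fraction=0.5 if het else 1.0))
    return reference, alu_intervals, gene_models, snps


def simulate_true_sites(
    config: SimulationConfig,
    reference: ReferenceSequence,
    alu_intervals: Sequence[GenomicInterval],
    exclude_positions: set[int] | None = None,
) -> list[TruthSite]:
    """Draw editable positions (ref A or T) with Beta-distributed rates.

    ``fraction_of_edit_sites_in_alu`` of the sites land inside Alu
    intervals (when enough editable Alu positions exist).  Positions in
    ``exclude_positions`` (typically the SNPs) are never chosen.
    """
    rng = np.random.default_rng(config.seed + 1)
    bases = np.array(list(reference.bases))
    editable = np.zeros(len(bases), dtype=bool)
    editable |= (bases == "A") | (bases == "T")
    if exclude_positions:
        editable[list(exclude_positions)] = False
    in_alu_mask = np.zeros(len(bases), dtype=bool)
    for iv in alu_intervals:
        in_alu_mask[iv.start:iv.end] = True
    alu_pool = np.flatnonzero(editable & in_alu_mask)
    out_pool = np.flatnonzero(editable & ~in_alu_mask)

    n_alu_sites = int(round(config.n_edit_sites * config.fraction_of_edit_sites_in_alu))
    n_alu_sites = min(n_alu_sites, len(alu_pool))
    n_out_sites = config.n_edit_sites - n_alu_sites
    if n_out_sites > len(out_pool):
        raise SizingError(
            "not enough editable non-Alu positions; reduce n_edit_sites or "
            "increase contig_length"
        )
    chosen_alu = rng.choice(alu_pool, size=n_alu_sites, replace=False) if n_alu_sites else np.array([], dtype=int)
    chosen_out = rng.choice(out_pool, size=n_out_sites, replace=False) if n_out_sites else np.array([], dtype=int)
    rates = rng.beta(config.edit_rate_alpha, config.edit_rate_beta,
                     size=config.n_edit_sites)
    sites = []
    for i, pos in enumerate(sorted({*map(int, chosen_alu), *map(int, chosen_out)})):
        ref_base = str(bases[pos])
        edit_type = "AG" if ref_base == "A" else "TC"
        sites.append(TruthSite(
            contig=reference.contig_name, position=pos, edit_type=edit_type,
            strand="+" if edit_type == "AG" else "-",
            rate=float(rates[i]), in_alu=bool(in_alu_mask[pos]),
        ))
    return sites


def build_truth(config: SimulationConfig) -> SimulationTruth:
    """Reference + features + SNPs + true sites in one seeded call."""
    reference, alu, genes, snps = simulate_reference(config)
    sites = simulate_true_sites(
        config, reference, alu,
        exclude_positions={s.position for s in snps},
    )
    return SimulationTruth(config=config, reference=reference,
                           alu_intervals=alu, gene_models=genes,
                           snps=snps, sites=sites)


# ---------------------------------------------------------------------------
# Per-sample pileups


def simulate_sample_pileup(
    truth: SimulationTruth,
    config: SimulationConfig,
    sample_seed: int,
    rate_scale: float = 1.0,
) -> list[PileupColumn]:
    """One sample's pileup columns over the whole contig.

    Depth per position is negative-binomial around ``mean_depth``.  At a
    truth site with rate q the alternate-base count is Binomial(depth, q')
    with q' = q(1-e) + (1-q)e/3 folding in the base-error rate e; at SNP
    positions the alternate fraction is the truth allele fraction; at all
    other positions each wrong base arises independently at rate e/3.
    """
    rng = np.random.default_rng(sample_seed)
    L = len(truth.reference)
    e = config.base_error_rate
    p_nb = config.depth_dispersion / (config.depth_dispersion + config.mean_depth)
    depth = rng.negative_binomial(config.depth_dispersion, p_nb, size=L)

    bases = np.array(list(truth.reference.bases))
    counts = {b: np.zeros(L, dtype=int) for b in "ACGT"}
    ref_count = depth.copy()
    # generic sequencing errors at every position
    err_total = rng.binomial(depth, e)
    ref_count -= err_total
    for pos in np.flatnonzero(err_total):
        wrong = [b for b in "ACGT" if b != bases[pos]]
        split = rng.multinomial(err_total[pos], [1 / 3] * 3)
        for b, k in zip(wrong, split):
            counts[b][pos] += int(k)

    special: dict[int, tuple[str, float]] = {}
    for site in truth.sites:
        q = min(site.rate * rate_scale, 1.0)
        q_eff = q * (1.0 - e) + (1.0 - q) * e / 3.0
        special[site.position] = (_EDIT_ALT[bases[site.position]], q_eff)
    for snp in truth.snps:
        special[snp.position] = (snp.alt, snp.alt_fraction)

    for pos, (alt, frac) in special.items():
        d = int(depth[pos])
        alt_n = int(rng.binomial(d, frac)) if d else 0
        # reset the column: alt + ref only (error already folded into frac)
        for b in "ACGT":
            counts[b][pos] = 0
        counts[alt][pos] = alt_n
        ref_count[pos] = d - alt_n

    for b in "ACGT":
        counts[b][bases == b] += ref_count[bases == b]

    columns = []
    contig = truth.reference.contig_name
    for pos in np.flatnonzero(depth > 0):
        pos = int(pos)
        col_counts = {b: int(counts[b][pos]) for b in "ACGT" if counts[b][pos] > 0}
        columns.append(PileupColumn(contig=contig, position=pos,
                                    ref_base=str(bases[pos]), counts=col_counts))
    return columns


# ---------------------------------------------------------------------------
# Minimal read simulation + SAM writer (exercises the alignment reader)


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    contig: str
    start: int  # 0-based leftmost reference position
    cigar: str
    sequence: str
    mapping_quality: int = 60


def simulate_reads(
    reference: ReferenceSequence,
    n_reads: int,
    rng: np.random.Generator,
    read_length: int = 40,
    mismatch_rate: float = 0.02,
    deletion_rate: float = 0.05,
    truth_sites: Sequence[TruthSite] = (),
    rate_scale: float = 1.0,
) -> list[SimulatedRead]:
    """Draw reads from the reference with optional edits, mismatches and
    single-base deletions (CIGARs use M and D only)."""
    site_rate = {s.position: min(s.rate * rate_scale, 1.0) for s in truth_sites}
    site_alt = {s.position: _EDIT_ALT[reference.bases[s.position]]
                for s in truth_sites}
    reads = []
    L = len(reference)
    for i in range(n_reads):
        start = int(rng.integers(0, max(L - read_length, 1)))
        seq_chars = []
        cigar_ops: list[tuple[int, str]] = []
        rpos = start
        consumed = 0
        while consumed < read_length and rpos < L:
            if rng.random() < deletion_rate and cigar_ops and cigar_ops[-1][1] == "M":
                cigar_ops.append((1, "D"))
                rpos += 1
                continue
            base = reference.bases[rpos]
            if rpos in site_rate and rng.random() < site_rate[rpos]:
                base = site_alt[rpos]
            elif rng.random() < mismatch_rate:
                base = str(rng.choice([b for b in "ACGT" if b != base]))
            seq_chars.append(base)
            if cigar_ops and cigar_ops[-1][1] == "M":
                cigar_ops[-1] = (cigar_ops[-1][0] + 1, "M")
            else:
                cigar_ops.append((1, "M"))
            rpos += 1
            consumed += 1
        while cigar_ops and cigar_ops[-1][1] == "D":
            cigar_ops.pop()
        if not cigar_ops:
            continue
        cigar = "".join(f"{n}{op}" for n, op in cigar_ops)
        reads.append(SimulatedRead(
            name=f"read{i}", contig=reference.contig_name, start=start,
            cigar=cigar, sequence="".join(seq_chars),
        ))
    return reads


def write_sam(
    reads: Sequence[SimulatedRead],
    reference: ReferenceSequence,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference.contig_name}\tLN:{len(reference)}\n")
        for read in reads:
            qual = "I" * len(read.sequence)
            fh.write(
                f"{read.name}\t0\t{read.contig}\t{read.start + 1}\t"
                f"{read.mapping_quality}\t{read.cigar}\t*\t0\t0\t"
                f"{read.sequence}\t{qual}\n"
            )


# ---------------------------------------------------------------------------
# Cohort


def simulate_cohort(
    config: SimulationConfig,
    per_patient_true_aei: Sequence[float] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the patient cohort and its ground truth.

    Pre-therapy AEIs are gamma-distributed to hit ``aei_mean_target`` /
    ``aei_sd_target`` (or supplied explicitly).  Death time is exponential
    with rate ``hazard_baseline * exp(hazard_slope * z)`` where z is the
    standardized pre-therapy AEI, so higher AEI means shorter survival.
    ADAR expression increases linearly in AEI with Gaussian noise; the
    immunogenicity covariates are log-normal and independent of AEI.
    Returns (cohort table with one row per patient-phase, truth table).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = config.cohort_n
    if per_patient_true_aei is not None:
        if len(per_patient_true_aei) != n:
            raise ValidationError("per_patient_true_aei length must equal cohort_n")
        pre_aei = np.asarray(per_patient_true_aei, dtype=float)
    else:
        shape = (config.aei_mean_target / config.aei_sd_target) ** 2
        scale = config.aei_mean_target / shape
        pre_aei = rng.gamma(shape, scale, size=n)
    on_aei = np.maximum(
        pre_aei + config.on_therapy_aei_shift
        + rng.normal(0.0, config.on_therapy_aei_noise_sd, size=n),
        0.0,
    )
    z = (pre_aei - config.aei_mean_target) / config.aei_sd_target
    hazard = config.hazard_baseline * np.exp(config.hazard_slope * z)
    death_time = rng.exponential(1.0 / hazard)
    if config.censor_time is not None:
        observed = np.minimum(death_time, config.censor_time)
        event = (death_time <= config.censor_time).astype(int)
    else:
        observed = death_time
        event = np.ones(n, dtype=int)
    adar = np.maximum(
        config.adar_intercept + config.adar_slope * pre_aei
        + rng.normal(0.0, config.adar_noise_sd, size=n),
        1e-3,
    )
    covs = {
        name: rng.lognormal(config.covariate_log_mean, config.covariate_log_sd, size=n)
        for name in ("mutation_load", "neoantigen_load", "neopeptide_load")
    }
    gzma = rng.lognormal(3.0, 0.8, size=n)
    prf1 = rng.lognormal(3.0, 0.8, size=n)

    rows = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        for phase, aei in (("pre", pre_aei[i]), ("on", on_aei[i])):
            rows.append({
                "patient_id": pid, "phase": phase,
                "survival_weeks": round(float(observed[i]), 4),
                "event": int(event[i]),
                "aei": round(float(aei), 4),
                "adar_expr": round(float(adar[i]), 4),
                "gzma_expr": round(float(gzma[i]), 4),
                "prf1_expr": round(float(prf1[i]), 4),
                "mutation_load": round(float(covs["mutation_load"][i]), 4),
                "neoantigen_load": round(float(covs["neoantigen_load"][i]), 4),
                "neopeptide_load": round(float(covs["neopeptide_load"][i]), 4),
            })
    cohort = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "patient_id": [f"P{i + 1:02d}" for i in range(n)],
        "true_pre_aei": pre_aei,
        "true_on_aei": on_aei,
        "hazard": hazard,
        "death_time": death_time,
        "observed_time": observed,
        "event": event,
    })
    return cohort, truth


# ---------------------------------------------------------------------------
# File emission


def write_simulation(truth: SimulationTruth, outdir: str | Path,
                     sample_pileups: dict[str, list[PileupColumn]] | None = None,
                     cohort: pd.DataFrame | None = None,
                     cohort_truth: pd.DataFrame | None = None) -> dict[str, Path]:
    """Emit every simulated artefact as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = outdir / "reference.fasta"
    write_fasta([truth.reference], paths["reference"])
    paths["alu"] = outdir / "alu.bed"
    write_bed(truth.alu_intervals, paths["alu"])
    paths["genes"] = outdir / "genes.tsv"
    write_gene_models(truth.gene_models, paths["genes"])
    paths["snps"] = outdir / "snps.vcf"
    write_vcf([(s.contig, s.position, s.ref, s.alt) for s in truth.snps],
              paths["snps"])

    site_rows = pd.DataFrame([{
        "contig": s.contig, "position": s.position + 1, "edit_type": s.edit_type,
        "strand": s.strand, "rate": s.rate, "in_alu": int(s.in_alu),
    } for s in truth.sites])
    paths["truth_sites"] = truth_dir / "sites.tsv"
    site_rows.to_csv(paths["truth_sites"], sep="\t", index=False)
    snp_rows = pd.DataFrame([{
        "contig": s.contig, "position": s.position + 1, "ref": s.ref,
        "alt": s.alt, "alt_fraction": s.alt_fraction,
    } for s in truth.snps])
    paths["truth_snps"] = truth_dir / "snps.tsv"
    snp_rows.to_csv(paths["truth_snps"], sep="\t", index=False)

    for sample_id, columns in (sample_pileups or {}).items():
        p = outdir / f"{sample_id}.pileup.tsv"
        write_pileup_tsv(columns, p)
        paths[f"pileup:{sample_id}"] = p
    if truth.sample_rate_scale:
        scale_rows = pd.DataFrame(
            sorted(truth.sample_rate_scale.items()),
            columns=["sample_id", "rate_scale"],
        )
        paths["truth_rate_scale"] = truth_dir / "sample_rate_scale.tsv"
        scale_rows.to_csv(paths["truth_rate_scale"], sep="\t", index=False)
    if cohort is not None:
        paths["cohort"] = outdir / "cohort.csv"
        cohort.to_csv(paths["cohort"], index=False)
    if cohort_truth is not None:
        paths["cohort_truth"] = truth_dir / "cohort.tsv"
        cohort_truth.to_csv(paths["cohort_truth"], sep="\t", index=False)
    return paths


def simulate_all(config: SimulationConfig, outdir: str | Path) -> tuple[SimulationTruth, dict[str, Path]]:
    """Full generation pass: reference, truth sites, cohort, and pileups for
    the first ``n_samples`` patients (pre-therapy), each scaled so its true
    AEI matches the patient's simulated AEI."""
    truth = build_truth(config)
    cohort, cohort_truth = simulate_cohort(config)
    truth.cohort = cohort
    truth.cohort_truth = cohort_truth
    base_sum = truth.true_aei()
    pileups: dict[str, list[PileupColumn]] = {}
    pre = cohort[cohort["phase"] == "pre"].reset_index(drop=True)
    for i in range(min(config.n_samples, len(pre))):
        sample_id = str(pre.loc[i, "patient_id"])
        target = float(pre.loc[i, "aei"])
        scale = target / base_sum if base_sum > 0 else 1.0
        truth.sample_rate_scale[sample_id] = scale
        pileups[sample_id] = simulate_sample_pileup(
            truth, config, sample_seed=config.seed + 1000 + i, rate_scale=scale,
        )
    paths = write_simulation(truth, outdir, sample_pileups=pileups,
                             cohort=cohort, cohort_truth=cohort_truth)
    return truth, paths
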