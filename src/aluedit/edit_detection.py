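"""Candidate editing-site calling and the three category filters.

A site is called only where the reference base is A with at least one G
observed (edit type ``AG``, strand ``+``) or the reference base is T with at
least one C observed (edit type ``TC``, strand ``-``).  All other mismatch
classes never produce sites.  Strand is inferred purely from the mismatch
class; gene-model strand is never consulted at detection time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError, ValidationError
from .io_formats import PileupColumn, ReferenceSequence

logger = logging.getLogger(__name__)


@dataclass
class EditSite:
    """One candidate A-to-I editing position."""

    contig: str
    position: int  # 0-based
    edit_type: str  # "AG" or "TC"
    strand: str  # "+" for AG, "-" for TC
    edit_count: int
    total_reads: int
    snp_filtered: bool = False
    region_class: str | None = None
    in_alu: bool | None = None

    def __post_init__(self) -> None:
        if self.edit_type not in ("AG", "TC"):
            raise ValidationError(f"invalid edit_type {self.edit_type!r}")
        expected_strand = "+" if self.edit_type == "AG" else "-"
        if self.strand != expected_strand:
            raise ValidationError(
                f"edit_type {self.edit_type} requires strand {expected_strand!r}"
            )
        if self.total_reads <= 0:
            raise ValidationError("total_reads must be positive")
        if not (0 <= self.edit_count <= self.total_reads):
            raise ValidationError("edit_count must lie in [0, total_reads]")

    @property
    def edit_ratio(self) -> float:
        return self.edit_count / self.total_reads

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity used in cross-sample comparisons."""
        return (self.contig, self.position, self.edit_type)


@dataclass(frozen=True)
class SiteCategory:
    """One of the three filter tiers on edit ratio and read counts.

    ``strict`` switches the boundary semantics from inclusive (>=, the
    formal definition) to exclusive (>); both appear in the source text.
    """

    name: str
    min_ratio: float
    min_reads: int
    min_edits: int = 1
    strict: bool = False

    def accepts(self, site: EditSite) -> bool:
        if self.strict:
            return (site.edit_ratio > self.min_ratio
                    and site.total_reads > self.min_reads
                    and site.edit_count >= self.min_edits)
        return (site.edit_ratio >= self.min_ratio
                and site.total_reads >= self.min_reads
                and site.edit_count >= self.min_edits)


ALL = SiteCategory("ALL", min_ratio=0.0, min_reads=1, min_edits=1)
STANDARD = SiteCategory("STANDARD", min_ratio=0.05, min_reads=5)
STRINGENT = SiteCategory("STRINGENT", min_ratio=0.25, min_reads=10)

CATEGORIES = {c.name: c for c in (ALL, STANDARD, STRINGENT)}


def get_category(name: str, strict: bool = False) -> SiteCategory:
    """Look up a category by (case-insensitive) name."""
    try:
        base = CATEGORIES[name.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unknown category {name!r}; choose from {sorted(CATEGORIES)}"
        ) from None
    if strict:
        return SiteCategory(base.name, base.min_ratio, base.min_reads,
                            base.min_edits, strict=True)
    return base


_EDIT_CLASSES = {"A": ("G", "AG", "+"), "T": ("C", "TC", "-")}


def call_candidate_sites(
    pileup_stream: Iterable[PileupColumn],
    reference: dict[str, ReferenceSequence],
) -> list[EditSite]:
    """Scan pileup columns for A>G (+) and T>C (-) mismatch sites.

    ``edit_count`` is the mismatch-base count and ``total_reads`` the full
    column depth, so other mismatches at the same column dilute the ratio
    but never produce sites of their own.  Columns whose reference base is
    N are skipped.
    """
    sites: list[EditSite] = []
    for col in pileup_stream:
        try:
            ref = reference[col.contig]
        except KeyError:
            raise ValidationError(
                f"pileup column on unknown contig {col.contig!r}"
            ) from None
        if not (0 <= col.position < len(ref)):
            raise ValidationError(
                f"pileup position {col.position} outside contig {col.contig}"
            )
        ref_base = ref.base_at(col.position)
        if ref_base != col.ref_base and col.ref_base != "N":
            raise ValidationError(
                f"pileup ref base {col.ref_base} disagrees with reference "
                f"{ref_base} at {col.contig}:{col.position}"
            )
        if ref_base == "N":
            continue
        edit_class = _EDIT_CLASSES.get(ref_base)
        if edit_class is None:
            continue
        alt_base, edit_type, strand = edit_class
        edits = col.count(alt_base)
        if edits == 0:
            continue
        depth = col.depth
        if edits > depth:
            raise ValidationError(
                f"counts exceed depth at {col.contig}:{col.position}"
            )
        sites.append(EditSite(
            contig=col.contig, position=col.position,
            edit_type=edit_type, strand=strand,
            edit_count=edits, total_reads=depth,
        ))
    return sites


def filter_known_snps(
    sites: Sequence[EditSite],
    snp_positions: set[tuple[str, int]],
) -> tuple[list[EditSite], int]:
    """Drop sites at known SNP positions; order of retained sites preserved.

    Retained sites get ``snp_filtered=True`` to record that they survived the
    filter.  Returns (retained, removed_count).
    """
    retained: list[EditSite] = []
    removed = 0
    for site in sites:
        if (site.contig, site.position) in snp_positions:
            removed += 1
        else:
            site.snp_filtered = True
            retained.append(site)
    logger.info("SNP filter: %d retained, %d removed", len(retained), removed)
    return retained, removed


def apply_category(
    sites: Sequence[EditSite], category: SiteCategory | str
) -> list[EditSite]:
    """Keep sites passing the category's ratio/read/edit thresholds."""
    if isinstance(category, str):
        category = get_category(category)
    for site in sites:
        if not (0.0 <= site.edit_ratio <= 1.0):
            raise ValidationError(
                f"site {site.contig}:{site.position} has ratio outside [0,1]"
            )
    kept = [s for s in sites if category.accepts(s)]
    logger.info("category %s: %d of %d sites retained",
                category.name, len(kept), len(sites))
    return kept
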