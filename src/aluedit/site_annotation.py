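"""Region-class and Alu annotation of called editing sites.

Region precedence when a position overlaps several feature classes:
utr3 > utr5 > exonic_cds > noncoding_or_RNA > intronic > intergenic.
When two genes overlap, the first by (start, gene_id) wins.  Strand is
ignored for overlap.  Annotation never alters counts or ratios.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import GeneModel, GenomicInterval
from .edit_detection import EditSite

logger = logging.getLogger(__name__)

REGION_CLASSES = [
    "utr3", "utr5", "exonic_cds", "noncoding_or_RNA", "intronic", "intergenic",
]
_PRECEDENCE = {name: rank for rank, name in enumerate(REGION_CLASSES)}


class _IntervalIndex:
    """Sorted-start interval lookup with running max-end for early exit.

    Point queries run in O(log n + k) for well-behaved interval sets, which
    satisfies the better-than-linear-scan contract.
    """

    def __init__(self, intervals: Sequence[tuple[int, int, object]]):
        # entries: (start, end, payload), sorted by start then end
        self._entries = sorted(intervals, key=lambda e: (e[0], e[1]))
        self._starts = [e[0] for e in self._entries]
        self._max_end = []
        running = 0
        for _, end, _ in self._entries:
            running = max(running, end)
            self._max_end.append(running)

    def query(self, position: int) -> list[object]:
        hits = []
        idx = bisect_right(self._starts, position) - 1
        while idx >= 0 and self._max_end[idx] > position:
            start, end, payload = self._entries[idx]
            if start <= position < end:
                hits.append(payload)
            idx -= 1
        hits.reverse()  # restore (start, end) order for determinism
        return hits


@dataclass
class AnnotationIndex:
    """Point-overlap lookups for gene features and Alu intervals."""

    _features: dict[str, _IntervalIndex]
    _alu: dict[str, _IntervalIndex]
    known_contigs: set[str]

    def region_class(self, contig: str, position: int) -> str:
        index = self._features.get(contig)
        if index is None:
            return "intergenic"
        hits = index.query(position)
        if not hits:
            return "intergenic"
        # payload: (precedence_rank, gene_start, gene_id, class_name)
        best = min(hits, key=lambda h: (h[0], h[1], h[2]))
        return best[3]

    def in_alu(self, contig: str, position: int) -> bool:
        index = self._alu.get(contig)
        return bool(index and index.query(position))


def _gene_feature_entries(gene: GeneModel) -> list[tuple[str, int, int, str]]:
    """Yield (contig, start, end, class_name) for a gene's features."""
    entries = []
    if gene.gene_type == "noncoding_or_RNA":
        # flat category: anywhere inside such a gene annotates to it
        for iv in gene.exons + gene.introns:
            entries.append((iv.contig, iv.start, iv.end, "noncoding_or_RNA"))
        return entries
    for iv in gene.utr3:
        entries.append((iv.contig, iv.start, iv.end, "utr3"))
    for iv in gene.utr5:
        entries.append((iv.contig, iv.start, iv.end, "utr5"))
    for iv in gene.exons:
        entries.append((iv.contig, iv.start, iv.end, "exonic_cds"))
    for iv in gene.introns:
        entries.append((iv.contig, iv.start, iv.end, "intronic"))
    return entries


def build_annotation_index(
    gene_models: Sequence[GeneModel],
    alu_intervals: Sequence[GenomicInterval],
    known_contigs: Iterable[str] | None = None,
) -> AnnotationIndex:
    """Build point-overlap indexes from gene models and Alu intervals.

    Intervals on contigs absent from ``known_contigs`` trigger a warning
    but are retained (queries on those contigs still resolve).
    """
    contigs = set(known_contigs) if known_contigs is not None else None
    by_contig: dict[str, list] = {}
    for gene in gene_models:
        gene_start = gene.start
        for contig, start, end, cls in _gene_feature_entries(gene):
            if contigs is not None and contig not in contigs:
                warnings.warn(f"gene {gene.gene_id} interval on unknown contig {contig!r}")
            payload = (_PRECEDENCE[cls], gene_start, gene.gene_id, cls)
            by_contig.setdefault(contig, []).append((start, end, payload))
    alu_by_contig: dict[str, list] = {}
    for iv in alu_intervals:
        if contigs is not None and iv.contig not in contigs:
            warnings.warn(f"Alu interval on unknown contig {iv.contig!r}")
        alu_by_contig.setdefault(iv.contig, []).append((iv.start, iv.end, iv))
    return AnnotationIndex(
        _features={c: _IntervalIndex(v) for c, v in by_contig.items()},
        _alu={c: _IntervalIndex(v) for c, v in alu_by_contig.items()},
        known_contigs=contigs or set(),
    )


def annotate_sites(
    sites: Sequence[EditSite], index: AnnotationIndex
) -> list[EditSite]:
    """Set region_class and in_alu on every site (in place) and return them."""
    for site in sites:
        site.region_class = index.region_class(site.contig, site.position)
        site.in_alu = index.in_alu(site.contig, site.position)
    return list(sites)


def summarize_by_region(sites: Sequence[EditSite]) -> pd.DataFrame:
    """Per-(region_class, in_alu) site count and mean reads/edits/ratio.

    Every cell of the region x Alu cross-tab appears, empty ones with
    count 0 and NaN means.
    """
    for site in sites:
        if site.region_class is None or site.in_alu is None:
            raise ValidationError(
                f"site {site.contig}:{site.position} is unannotated; "
                "run annotate_sites first"
            )
    rows = []
    for region in REGION_CLASSES:
        for in_alu in (False, True):
            cell = [s for s in sites
                    if s.region_class == region and s.in_alu is in_alu]
            n = len(cell)
            rows.append({
                "region_class": region,
                "in_alu": in_alu,
                "n_sites": n,
                "mean_reads": (sum(s.total_reads for s in cell) / n) if n else float("nan"),
                "mean_edits": (sum(s.edit_count for s in cell) / n) if n else float("nan"),
                "mean_ratio": (sum(s.edit_ratio for s in cell) / n) if n else float("nan"),
            })
    return pd.DataFrame(rows)


@dataclass
class SiteSetComparison:
    """Membership tallies of site keys across >= 2 groups."""

    unique_counts: dict[str, int]
    shared_count: int
    unique_sites: dict[str, set[tuple[str, int, str]]]
    shared_sites: set[tuple[str, int, str]]


def site_set_comparison(
    profiles_by_group: Mapping[str, Iterable],
) -> SiteSetComparison:
    """Count site keys unique to one group vs present in several.

    ``profiles_by_group`` maps a group name to an iterable of
    SampleEditingProfile objects (or any objects with a ``sites`` list);
    a group's site set is the union over its profiles.  Site identity is
    (contig, position, edit_type).
    """
    if len(profiles_by_group) < 2:
        raise ValidationError("site_set_comparison needs at least two groups")
    group_keys: dict[str, set[tuple[str, int, str]]] = {}
    for group, profiles in profiles_by_group.items():
        keys: set[tuple[str, int, str]] = set()
        for profile in profiles:
            sites = getattr(profile, "sites", profile)
            keys.update(s.key for s in sites)
        group_keys[group] = keys
    membership: dict[tuple[str, int, str], int] = {}
    for keys in group_keys.values():
        for key in keys:
            membership[key] = membership.get(key, 0) + 1
    shared = {k for k, n in membership.items() if n > 1}
    unique_sites = {g: {k for k in keys if membership[k] == 1}
                    for g, keys in group_keys.items()}
    return SiteSetComparison(
        unique_counts={g: len(s) for g, s in unique_sites.items()},
        shared_count=len(shared),
        unique_sites=unique_sites,
        shared_sites=shared,
    )
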