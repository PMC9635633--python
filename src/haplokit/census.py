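"""Haplotype bookkeeping: locus census, gene density, repeat summarization,
boundary arithmetic and protein-identity locus typing.

Percentages are computed from unrounded bp sums and rounded half-up to two
decimals; grouped rows additionally carry the table convention of summing the
already-rounded member rows (``percent_table``), which is how printed totals
in the source tables are formed.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError
from .io_core import FeatureRecord, RepeatRecord, translate_cds

logger = logging.getLogger(__name__)

TRANSPOSABLE_CLASSES = ("LTR", "LINE", "DNA_transposon")
TANDEM_CLASSES = ("tandem",)
OTHER_CLASSES = ("small_RNA", "satellite", "simple", "low_complexity")


def _round_half_up(value: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# locus census
# ---------------------------------------------------------------------------


@dataclass
class CensusReport:
    """Per (contig, family) locus and pseudogene counts with totals."""

    table: pd.DataFrame  # index family, columns contig ids + 'Total'
    pseudo_table: pd.DataFrame
    grand_total: int
    grand_pseudo: int

    def family_total(self, family: str) -> int:
        return int(self.table.loc[family, "Total"])

    def to_tsv(self, path) -> None:
        merged = self.table.astype(str)
        for fam in merged.index:
            for col in merged.columns:
                merged.loc[fam, col] = (
                    f"{self.table.loc[fam, col]} ({self.pseudo_table.loc[fam, col]}P)"
                )
        totals = {
            col: f"{int(self.table[col].sum())} ({int(self.pseudo_table[col].sum())}P)"
            for col in merged.columns
        }
        merged.loc["Total"] = totals
        merged.to_csv(path, sep="\t", index_label="family")


def count_loci(
    features: Sequence[FeatureRecord], contigs: Sequence[str]
) -> CensusReport:
    """Tabulate loci (and pseudogene subtotals) by contig and family."""
    unknown = sorted(
        {f.locus_id for f in features if f.seq_id not in set(contigs)}
    )
    if unknown:
        raise DomainError(f"features on unknown contigs: {unknown}")
    families = sorted({f.family for f in features})
    table = pd.DataFrame(0, index=families, columns=list(contigs), dtype=int)
    pseudo = pd.DataFrame(0, index=families, columns=list(contigs), dtype=int)
    for f in features:
        table.loc[f.family, f.seq_id] += 1
        if f.pseudogene:
            pseudo.loc[f.family, f.seq_id] += 1
    table["Total"] = table.sum(axis=1)
    pseudo["Total"] = pseudo.sum(axis=1)
    return CensusReport(
        table=table,
        pseudo_table=pseudo,
        grand_total=int(table["Total"].sum()),
        grand_pseudo=int(pseudo["Total"].sum()),
    )


def gene_density(n_loci: int, region_length_mb: float) -> int:
    """Loci per Mb, rounded half away from zero to the nearest integer."""
    if region_length_mb <= 0:
        raise DomainError(f"region length must be positive, got {region_length_mb}")
    return int(_round_half_up(n_loci / region_length_mb, 0))


# ---------------------------------------------------------------------------
# repeat summary
# ---------------------------------------------------------------------------


@dataclass
class RepeatClassRow:
    repeat_class: str
    count: int
    total_bp: int
    percent: float  # 100 * bp / region, half-up 2 dp


@dataclass
class RepeatGroupRow:
    group: str
    count: int
    total_bp: int
    percent: float  # recomputed from unrounded bp sum
    percent_table: float  # sum of member rows' rounded percents (table convention)


@dataclass
class RepeatSummary:
    region_length_bp: int
    classes: dict[str, RepeatClassRow]
    groups: dict[str, RepeatGroupRow]
    n_other_records: int = 0

    def class_percent(self, repeat_class: str) -> float:
        row = self.classes.get(repeat_class)
        return row.percent if row else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": r.repeat_class,
                "kind": "class",
                "count": r.count,
                "total_bp": r.total_bp,
                "percent": f"{r.percent:.2f}",
            }
            for r in self.classes.values()
        ] + [
            {
                "name": g.group,
                "kind": "group",
                "count": g.count,
                "total_bp": g.total_bp,
                "percent": f"{g.percent_table:.2f}",
            }
            for g in self.groups.values()
        ]
        return pd.DataFrame(rows)


def summarize_repeats(
    repeats: Sequence[RepeatRecord], region_length_bp: int
) -> RepeatSummary:
    """Per-class repeat counts, masked bp and percent of region.

    Grouped rows (transposable elements, tandem repeats, other repeats) carry
    two percentages: one recomputed from the summed bp, and one formed by
    summing the rounded member-class percents (the printed-table convention).
    """
    if region_length_bp <= 0:
        raise DomainError("region length must be positive")
    for r in repeats:
        if r.end > region_length_bp and len({x.seq_id for x in repeats}) == 1:
            raise DomainError(
                f"repeat at {r.start}-{r.end} extends beyond region {region_length_bp}"
            )
    classes: dict[str, RepeatClassRow] = {}
    n_other = 0
    for cls in TRANSPOSABLE_CLASSES + TANDEM_CLASSES + OTHER_CLASSES:
        members = [r for r in repeats if r.repeat_class == cls]
        bp = sum(r.length for r in members)
        classes[cls] = RepeatClassRow(
            repeat_class=cls,
            count=len(members),
            total_bp=bp,
            percent=_round_half_up(100.0 * bp / region_length_bp, 2),
        )
    n_other = sum(1 for r in repeats if r.repeat_class == "other")
    if n_other:
        logger.warning("%d records in 'other' bucket excluded from summary", n_other)

    groups: dict[str, RepeatGroupRow] = {}
    for group, members in (
        ("transposable_elements", TRANSPOSABLE_CLASSES),
        ("tandem_repeats", TANDEM_CLASSES),
        ("other_repeats", OTHER_CLASSES),
    ):
        rows = [classes[c] for c in members]
        bp = sum(r.total_bp for r in rows)
        groups[group] = RepeatGroupRow(
            group=group,
            count=sum(r.count for r in rows),
            total_bp=bp,
            percent=_round_half_up(100.0 * bp / region_length_bp, 2),
            percent_table=_round_half_up(sum(r.percent for r in rows), 2),
        )
    return RepeatSummary(
        region_length_bp=region_length_bp,
        classes=classes,
        groups=groups,
        n_other_records=n_other,
    )


# ---------------------------------------------------------------------------
# boundary and contig arithmetic
# ---------------------------------------------------------------------------


def boundary_gap(upstream: FeatureRecord, downstream: FeatureRecord) -> int:
    """Distance from the end of one feature to the start of the next
    (downstream.start - upstream.end; adjacent features are 1 apart)."""
    if upstream.seq_id != downstream.seq_id:
        raise DomainError("features lie on different sequences")
    if upstream.end >= downstream.start:
        raise DomainError(
            f"features overlap or are mis-ordered: "
            f"{upstream.locus_id} ends {upstream.end}, "
            f"{downstream.locus_id} starts {downstream.start}"
        )
    return downstream.start - upstream.end


@dataclass
class ContigTotals:
    overall_bp: int
    region_bp: int  # overall minus the excluded (e.g. rDNA array) span
    per_contig_region_bp: list[int]


def contig_arithmetic(
    contig_lengths: Sequence[int], nor_length_bp: int, nor_contig: int = 0
) -> ContigTotals:
    """Overall bp total, region total net of an excluded span, and per-contig
    region portions. The excluded span is attributed to ``nor_contig``."""
    if any(length <= 0 for length in contig_lengths):
        raise DomainError("contig lengths must be positive")
    if nor_length_bp < 0:
        raise DomainError("excluded span must be non-negative")
    if nor_length_bp > contig_lengths[nor_contig]:
        raise DomainError(
            f"excluded span {nor_length_bp} exceeds contig {nor_contig} "
            f"length {contig_lengths[nor_contig]}"
        )
    overall = sum(contig_lengths)
    portions = list(contig_lengths)
    portions[nor_contig] -= nor_length_bp
    return ContigTotals(
        overall_bp=overall,
        region_bp=overall - nor_length_bp,
        per_contig_region_bp=portions,
    )


# ---------------------------------------------------------------------------
# locus typing by predicted-protein identity
# ---------------------------------------------------------------------------


@dataclass
class TypeClustering:
    """Groups of loci sharing an identical predicted protein."""

    types: dict[str, list[str]]  # label -> locus_ids in genomic order
    excluded: list[str] = field(default_factory=list)

    @property
    def n_types(self) -> int:
        return len(self.types)

    def copies(self, label: str) -> int:
        return len(self.types[label])


def _type_labels() -> Iterable[str]:
    letters = string.ascii_lowercase
    for ch in letters:
        yield ch
    for a in letters:  # beyond 'z': aa, ab, ...
        for b in letters:
            yield a + b


def cluster_types(
    loci: Sequence[FeatureRecord],
    cds_by_locus: Mapping[str, str],
    contig_order: Sequence[str] | None = None,
) -> TypeClustering:
    """Group full-length loci into types by exact predicted-protein identity.

    Labels "a", "b", ... are assigned in order of first genomic occurrence
    (contig order, then start coordinate). Untranslatable loci are excluded
    with a warning and listed in the result.
    """
    full = [f for f in loci if f.full_length]
    if contig_order is None:
        contig_order = sorted({f.seq_id for f in full})
    rank = {sid: i for i, sid in enumerate(contig_order)}
    ordered = sorted(full, key=lambda f: (rank.get(f.seq_id, len(rank)), f.start))

    proteins: dict[str, str] = {}
    excluded: list[str] = []
    for f in ordered:
        cds = cds_by_locus.get(f.locus_id)
        if cds is None:
            excluded.append(f.locus_id)
            logger.warning("locus %s has no CDS; excluded from typing", f.locus_id)
            continue
        try:
            prot = translate_cds(cds)
        except DomainError:
            excluded.append(f.locus_id)
            logger.warning("locus %s untranslatable; excluded from typing", f.locus_id)
            continue
        proteins[f.locus_id] = prot

    types: dict[str, list[str]] = {}
    seen: dict[str, str] = {}  # protein -> label
    labels = _type_labels()
    for f in ordered:
        if f.locus_id not in proteins:
            continue
        prot = proteins[f.locus_id]
        if prot not in seen:
            seen[prot] = next(labels)
            types[seen[prot]] = []
        types[seen[prot]].append(f.locus_id)
    return TypeClustering(types=types, excluded=excluded)
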