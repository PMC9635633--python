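"""Wu-Kabat variability-index profiling of protein alignments.

For each alignment column the index is ``VI = k / (n_max / N)`` where ``k``
is the number of distinct non-gap residues, ``n_max`` the count of the most
common residue, and ``N`` the number of non-gap rows. Columns with
``VI >= threshold`` (default 6, inclusive) are called polymorphic. Gaps are
excluded from all three quantities.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import DomainError
from .io_core import MsaAlignment

GAP_CHARS = frozenset("-.")

DEFAULT_THRESHOLD = 6.0


@dataclass(frozen=True)
class ColumnStat:
    position: int  # 1-based alignment column
    k: int
    n_max: int
    n_col: int
    vi: float | None  # None when the column is all-gap
    polymorphic: bool


@dataclass
class VariabilityProfile:
    alignment_id: str
    threshold: float
    columns: list[ColumnStat]

    @property
    def polymorphic_positions(self) -> list[int]:
        return [c.position for c in self.columns if c.polymorphic]

    def vi_values(self) -> list[float | None]:
        return [c.vi for c in self.columns]


def compute_vi(
    msa: MsaAlignment, threshold: float = DEFAULT_THRESHOLD, alignment_id: str = ""
) -> VariabilityProfile:
    """Per-column Wu-Kabat statistics with an inclusive polymorphism call."""
    if msa.n_rows < 2:
        raise DomainError("variability needs at least 2 rows")
    columns: list[ColumnStat] = []
    any_defined = False
    for j in range(msa.width):
        tally = Counter(
            row[j] for row in msa.rows if row[j] not in GAP_CHARS
        )
        n_col = sum(tally.values())
        if n_col == 0:
            columns.append(ColumnStat(j + 1, 0, 0, 0, None, False))
            continue
        any_defined = True
        k = len(tally)
        n_max = max(tally.values())
        vi = k / (n_max / n_col)
        columns.append(ColumnStat(j + 1, k, n_max, n_col, vi, vi >= threshold))
    if not any_defined:
        raise DomainError("all-gap alignment: profile undefined")
    return VariabilityProfile(
        alignment_id=alignment_id or (msa.ids[0] + "+"), threshold=threshold,
        columns=columns,
    )


@dataclass
class PolymorphismComparison:
    group_a: str
    group_b: str
    shared_positions_a: list[int]  # shared columns in group A reference numbering
    shared_positions_b: list[int]
    specific_a: list[int]
    specific_b: list[int]


def _reference_numbering(msa: MsaAlignment, ref_id: str) -> dict[int, int]:
    """Map alignment column (0-based) -> 1-based position in the reference row,
    skipping columns where the reference has a gap."""
    try:
        ref_row = msa.rows[msa.ids.index(ref_id)]
    except ValueError:
        raise DomainError(f"reference id {ref_id!r} not in alignment") from None
    mapping: dict[int, int] = {}
    pos = 0
    for j, ch in enumerate(ref_row):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[j] = pos
    return mapping


def compare_polymorphic_sets(
    joint_msa: MsaAlignment,
    group_a: str,
    group_b: str,
    ref_a: str,
    ref_b: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> PolymorphismComparison:
    """Compare polymorphic column sets of two groups aligned jointly.

    VI is computed within each group separately on the joint columns; shared
    positions are columns polymorphic in both groups, reported in each
    group's reference-row numbering (reference-gap columns are unnumbered
    and never reported).
    """
    idx_a = [i for i, g in enumerate(joint_msa.groups) if g == group_a]
    idx_b = [i for i, g in enumerate(joint_msa.groups) if g == group_b]
    for name, idx in ((group_a, idx_a), (group_b, idx_b)):
        if len(idx) < 2:
            raise DomainError(f"group {name!r} has <2 rows")
    prof_a = compute_vi(joint_msa.subset(idx_a), threshold, alignment_id=group_a)
    prof_b = compute_vi(joint_msa.subset(idx_b), threshold, alignment_id=group_b)
    poly_a = {c.position - 1 for c in prof_a.columns if c.polymorphic}
    poly_b = {c.position - 1 for c in prof_b.columns if c.polymorphic}
    num_a = _reference_numbering(joint_msa, ref_a)
    num_b = _reference_numbering(joint_msa, ref_b)
    shared = poly_a & poly_b
    return PolymorphismComparison(
        group_a=group_a,
        group_b=group_b,
        shared_positions_a=sorted(num_a[j] for j in shared if j in num_a),
        shared_positions_b=sorted(num_b[j] for j in shared if j in num_b),
        specific_a=sorted(num_a[j] for j in (poly_a - poly_b) if j in num_a),
        specific_b=sorted(num_b[j] for j in (poly_b - poly_a) if j in num_b),
    )


PROFILE_COLUMNS = ("position", "k", "n_max", "N_col", "VI", "call")


def profile_report(profile: VariabilityProfile, path: str | Path) -> None:
    """Write the profile as a TSV, one row per alignment column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(PROFILE_COLUMNS)
        for c in profile.columns:
            if c.vi is None:
                writer.writerow([c.position, "NA", "NA", "NA", "NA", "NA"])
            else:
                writer.writerow(
                    [
                        c.position,
                        c.k,
                        c.n_max,
                        c.n_col,
                        repr(c.vi),
                        "polymorphic" if c.polymorphic else "conserved",
                    ]
                )


def read_profile_report(path: str | Path, threshold: float = DEFAULT_THRESHOLD,
                        alignment_id: str = "") -> VariabilityProfile:
    """Parse a profile TSV back into a VariabilityProfile (round-trip)."""
    columns: list[ColumnStat] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["VI"] == "NA":
                columns.append(ColumnStat(int(row["position"]), 0, 0, 0, None, False))
            else:
                columns.append(
                    ColumnStat(
                        position=int(row["position"]),
                        k=int(row["k"]),
                        n_max=int(row["n_max"]),
                        n_col=int(row["N_col"]),
                        vi=float(row["VI"]),
                        polymorphic=row["call"] == "polymorphic",
                    )
                )
    return VariabilityProfile(alignment_id=alignment_id, threshold=threshold,
                              columns=columns)
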