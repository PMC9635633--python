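"""K-mer anchored dot plots, anchor chaining and duplicated-block calling.

Exact shared k-mers (both orientations) replace inexact alignment seeds;
tolerance to divergence between block copies comes from chaining anchors
across gaps, not from inexact matching. For forward anchors collinearity
means a near-constant diagonal ``pos_b - pos_a``; for inverted anchors a
near-constant anti-diagonal ``pos_b + pos_a``.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DomainError
from .io_core import GenomicSequence, reverse_complement

FORWARD = "forward"
INVERTED = "inverted"

DEFAULT_K = 21
DEFAULT_MAX_GAP = 2000
DEFAULT_MIN_SPAN = 300
DEFAULT_MIN_BLOCK = 20000
DEFAULT_FULL_THRESHOLD = 0.90


@dataclass(frozen=True)
class AnchorMatch:
    pos_a: int  # 1-based k-mer start in sequence A
    pos_b: int
    orientation: str


@dataclass(frozen=True)
class SegmentChain:
    seq_a: str
    seq_b: str
    interval_a: tuple[int, int]  # 1-based inclusive bp
    interval_b: tuple[int, int]
    orientation: str
    n_anchors: int
    span_bp: int


@dataclass(frozen=True)
class BlockCopy:
    seq_id: str
    interval: tuple[int, int]
    orientation: str
    completeness: float

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1

    def is_full(self, full_threshold: float = DEFAULT_FULL_THRESHOLD) -> bool:
        return self.completeness >= full_threshold


@dataclass
class DuplicationBlock:
    block_id: str
    archetype_length_bp: int
    copies: list[BlockCopy]


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def _kmer_index(residues: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(residues) - k + 1):
        kmer = residues[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i + 1)
    return index


def find_anchors(
    seq_a: GenomicSequence, seq_b: GenomicSequence, k: int = DEFAULT_K
) -> list[AnchorMatch]:
    """All exact shared k-mers between two sequences, in both orientations.

    K-mers containing N are skipped. In a self-comparison the trivial
    identity diagonal (``pos_a == pos_b``, forward) is excluded.
    """
    if k < 8:
        raise DomainError(f"k must be >= 8, got {k}")
    if len(seq_a) < k or len(seq_b) < k:
        raise DomainError("k exceeds a sequence length")
    is_self = seq_a.id == seq_b.id and seq_a.residues == seq_b.residues
    index = _kmer_index(seq_a.residues, k)
    anchors: list[AnchorMatch] = []
    res_b = seq_b.residues
    for j in range(len(res_b) - k + 1):
        kmer = res_b[j : j + k]
        if "N" in kmer:
            continue
        pos_b = j + 1
        for pos_a in index.get(kmer, ()):
            if is_self and pos_a == pos_b:
                continue
            anchors.append(AnchorMatch(pos_a, pos_b, FORWARD))
        rc = reverse_complement(kmer)
        for pos_a in index.get(rc, ()):
            anchors.append(AnchorMatch(pos_a, pos_b, INVERTED))
    return anchors


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


@dataclass
class _ProtoChain:
    key: int  # diagonal (forward) or anti-diagonal (inverted)
    a_min: int
    a_max: int
    b_min: int
    b_max: int
    n: int


def _interval_gap(lo1: int, hi1: int, lo2: int, hi2: int) -> int:
    return max(0, max(lo1, lo2) - min(hi1, hi2))


def chain_anchors(
    anchors: Sequence[AnchorMatch],
    k: int = DEFAULT_K,
    seq_a: str = "a",
    seq_b: str = "b",
    max_gap_bp: int = DEFAULT_MAX_GAP,
    min_span_bp: int = DEFAULT_MIN_SPAN,
) -> list[SegmentChain]:
    """Single-linkage chaining of same-orientation anchors.

    Anchors join a chain when their diagonal offsets differ by at most
    ``max_gap_bp`` and their positions are within ``max_gap_bp``. Chains
    spanning less than ``min_span_bp`` (on the shorter side) are discarded.
    """
    chains: list[SegmentChain] = []
    for orientation in (FORWARD, INVERTED):
        sub = [a for a in anchors if a.orientation == orientation]
        if not sub:
            continue
        by_key: dict[int, list[AnchorMatch]] = defaultdict(list)
        for a in sub:
            key = a.pos_b - a.pos_a if orientation == FORWARD else a.pos_b + a.pos_a
            by_key[key].append(a)
        # pass 1: split each exact diagonal into runs with pos gaps <= max_gap
        protos: list[_ProtoChain] = []
        for key, group in by_key.items():
            group.sort(key=lambda a: a.pos_a)
            run = [group[0]]
            for a in group[1:]:
                if a.pos_a - run[-1].pos_a > max_gap_bp:
                    protos.append(_close_run(key, run))
                    run = []
                run.append(a)
            protos.append(_close_run(key, run))
        # pass 2: single-linkage merge of proto-chains across nearby diagonals
        merged = _merge_protos(protos, max_gap_bp)
        for p in merged:
            ia = (p.a_min, p.a_max + k - 1)
            ib = (p.b_min, p.b_max + k - 1)
            span = min(ia[1] - ia[0] + 1, ib[1] - ib[0] + 1)
            if span >= min_span_bp:
                chains.append(
                    SegmentChain(
                        seq_a=seq_a,
                        seq_b=seq_b,
                        interval_a=ia,
                        interval_b=ib,
                        orientation=orientation,
                        n_anchors=p.n,
                        span_bp=span,
                    )
                )
    chains.sort(key=lambda c: (c.interval_a, c.interval_b, c.orientation))
    return chains


def _close_run(key: int, run: list[AnchorMatch]) -> _ProtoChain:
    return _ProtoChain(
        key=key,
        a_min=min(a.pos_a for a in run),
        a_max=max(a.pos_a for a in run),
        b_min=min(a.pos_b for a in run),
        b_max=max(a.pos_b for a in run),
        n=len(run),
    )


def _merge_protos(protos: list[_ProtoChain], max_gap_bp: int) -> list[_ProtoChain]:
    n = len(protos)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    protos_sorted = sorted(range(n), key=lambda i: protos[i].key)
    for ii in range(n):
        i = protos_sorted[ii]
        for jj in range(ii + 1, n):
            j = protos_sorted[jj]
            if protos[j].key - protos[i].key > max_gap_bp:
                break
            pi, pj = protos[i], protos[j]
            if _interval_gap(pi.a_min, pi.a_max, pj.a_min, pj.a_max) <= max_gap_bp:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[_ProtoChain]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(protos[i])
    out = []
    for members in groups.values():
        out.append(
            _ProtoChain(
                key=members[0].key,
                a_min=min(m.a_min for m in members),
                a_max=max(m.a_max for m in members),
                b_min=min(m.b_min for m in members),
                b_max=max(m.b_max for m in members),
                n=sum(m.n for m in members),
            )
        )
    return out


def chain_pair(
    seq_a: GenomicSequence,
    seq_b: GenomicSequence,
    k: int = DEFAULT_K,
    max_gap_bp: int = DEFAULT_MAX_GAP,
    min_span_bp: int = DEFAULT_MIN_SPAN,
) -> list[SegmentChain]:
    """Convenience: find_anchors + chain_anchors for one sequence pair."""
    anchors = find_anchors(seq_a, seq_b, k=k)
    return chain_anchors(
        anchors, k=k, seq_a=seq_a.id, seq_b=seq_b.id,
        max_gap_bp=max_gap_bp, min_span_bp=min_span_bp,
    )


def chain_all_pairs(
    sequences: Sequence[GenomicSequence],
    k: int = DEFAULT_K,
    max_gap_bp: int = DEFAULT_MAX_GAP,
    min_span_bp: int = DEFAULT_MIN_SPAN,
) -> list[SegmentChain]:
    """Chains over every sequence pair including self-comparisons."""
    chains: list[SegmentChain] = []
    for i, a in enumerate(sequences):
        for b in sequences[i:]:
            chains.extend(
                chain_pair(a, b, k=k, max_gap_bp=max_gap_bp, min_span_bp=min_span_bp)
            )
    return chains


# ---------------------------------------------------------------------------
# block calling
# ---------------------------------------------------------------------------


def _reciprocal_overlap(i1: tuple[int, int], i2: tuple[int, int]) -> float:
    ov = min(i1[1], i2[1]) - max(i1[0], i2[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (i1[1] - i1[0] + 1), ov / (i2[1] - i2[0] + 1))


def call_blocks(
    chains: Sequence[SegmentChain],
    min_block_bp: int = DEFAULT_MIN_BLOCK,
    full_threshold: float = DEFAULT_FULL_THRESHOLD,
) -> list[DuplicationBlock]:
    """Group long chains into duplicated blocks.

    Chain endpoints on the same sequence are merged into one copy when they
    reciprocally overlap by >= 50% (single linkage); copies connected by a
    chain belong to one block. The archetype is the longest copy; every
    copy's orientation is resolved relative to the archetype by propagating
    chain orientations through the block graph.
    """
    long_chains = [c for c in chains if c.span_bp >= min_block_bp]
    if not long_chains:
        return []
    # endpoints: (seq_id, interval); two per chain
    endpoints: list[tuple[str, tuple[int, int]]] = []
    chain_ends: list[tuple[int, int]] = []
    for c in long_chains:
        endpoints.append((c.seq_a, c.interval_a))
        endpoints.append((c.seq_b, c.interval_b))
        chain_ends.append((len(endpoints) - 2, len(endpoints) - 1))

    n = len(endpoints)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(n):
        for j in range(i + 1, n):
            if endpoints[i][0] != endpoints[j][0]:
                continue
            if _reciprocal_overlap(endpoints[i][1], endpoints[j][1]) >= 0.5:
                union(i, j)

    # copy clusters
    cluster_of = {i: find(i) for i in range(n)}
    cluster_interval: dict[int, tuple[str, int, int]] = {}
    for i in range(n):
        root = cluster_of[i]
        sid, (lo, hi) = endpoints[i]
        if root in cluster_interval:
            _, clo, chi = cluster_interval[root]
            cluster_interval[root] = (sid, min(clo, lo), max(chi, hi))
        else:
            cluster_interval[root] = (sid, lo, hi)

    # block graph: edges between copy clusters labelled by chain orientation
    edges: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for (idx_a, idx_b), chain in zip(chain_ends, long_chains):
        ca, cb = cluster_of[idx_a], cluster_of[idx_b]
        if ca == cb:
            continue  # chain folds onto one copy (e.g. adjacent inverted repeat halves)
        edges[ca].append((cb, chain.orientation))
        edges[cb].append((ca, chain.orientation))

    # connected components with orientation parity
    blocks: list[DuplicationBlock] = []
    visited: set[int] = set()
    for root in sorted(cluster_interval, key=lambda r: (cluster_interval[r][0],
                                                        cluster_interval[r][1])):
        if root in visited:
            continue
        component: list[int] = []
        parity: dict[int, str] = {root: FORWARD}
        stack = [root]
        visited.add(root)
        while stack:
            node = stack.pop()
            component.append(node)
            for nbr, orientation in edges[node]:
                if nbr not in visited:
                    visited.add(nbr)
                    parity[nbr] = (
                        parity[node]
                        if orientation == FORWARD
                        else (INVERTED if parity[node] == FORWARD else FORWARD)
                    )
                    stack.append(nbr)
        if len(component) < 2:
            continue
        ivals = {c: cluster_interval[c] for c in component}
        archetype = max(component, key=lambda c: ivals[c][2] - ivals[c][1] + 1)
        arch_len = ivals[archetype][2] - ivals[archetype][1] + 1
        # orientations reported relative to the archetype copy
        flip = parity[archetype] == INVERTED
        copies = []
        for c in component:
            sid, lo, hi = ivals[c]
            orient = parity[c]
            if flip:
                orient = INVERTED if orient == FORWARD else FORWARD
            copies.append(
                BlockCopy(
                    seq_id=sid,
                    interval=(lo, hi),
                    orientation="direct" if orient == FORWARD else "inverted",
                    completeness=min(1.0, (hi - lo + 1) / arch_len),
                )
            )
        copies.sort(key=lambda cp: (cp.seq_id, cp.interval))
        blocks.append(
            DuplicationBlock(
                block_id="", archetype_length_bp=arch_len, copies=copies
            )
        )
    blocks.sort(key=lambda b: (b.copies[0].seq_id, b.copies[0].interval))
    for i, b in enumerate(blocks, start=1):
        b.block_id = f"block_{i}"
    _ = full_threshold  # copies expose is_full(full_threshold)
    return blocks


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_CHAIN_COLUMNS = (
    "seq_a", "a_start", "a_end", "seq_b", "b_start", "b_end",
    "orientation", "n_anchors", "span_bp",
)


def write_chains_tsv(chains: Iterable[SegmentChain], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_CHAIN_COLUMNS)
        for c in chains:
            writer.writerow(
                [c.seq_a, c.interval_a[0], c.interval_a[1], c.seq_b,
                 c.interval_b[0], c.interval_b[1], c.orientation,
                 c.n_anchors, c.span_bp]
            )


def read_chains_tsv(path: str | Path) -> list[SegmentChain]:
    chains: list[SegmentChain] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            chains.append(
                SegmentChain(
                    seq_a=row["seq_a"],
                    seq_b=row["seq_b"],
                    interval_a=(int(row["a_start"]), int(row["a_end"])),
                    interval_b=(int(row["b_start"]), int(row["b_end"])),
                    orientation=row["orientation"],
                    n_anchors=int(row["n_anchors"]),
                    span_bp=int(row["span_bp"]),
                )
            )
    return chains


def write_blocks_tsv(blocks: Iterable[DuplicationBlock], path: str | Path,
                     full_threshold: float = DEFAULT_FULL_THRESHOLD) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["block_id", "archetype_bp", "seq_id", "start", "end",
             "orientation", "completeness", "full"]
        )
        for b in blocks:
            for cp in b.copies:
                writer.writerow(
                    [b.block_id, b.archetype_length_bp, cp.seq_id,
                     cp.interval[0], cp.interval[1], cp.orientation,
                     f"{cp.completeness:.3f}", int(cp.is_full(full_threshold))]
                )


def export_dotplot(
    chains: Sequence[SegmentChain],
    path: str | Path,
    seq_a_len: int | None = None,
    gene_features=None,
    self_plot: bool = False,
) -> None:
    """Render chains as a dot plot: forward traces rise, inverted traces fall.

    Self plots always include the main diagonal reference line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    for c in chains:
        (a0, a1), (b0, b1) = c.interval_a, c.interval_b
        if c.orientation == FORWARD:
            ax.plot([a0, a1], [b0, b1], color="tab:blue", lw=1)
        else:
            ax.plot([a0, a1], [b1, b0], color="tab:red", lw=1)
    if self_plot:
        hi = seq_a_len or max(
            [c.interval_a[1] for c in chains] + [c.interval_b[1] for c in chains],
            default=1,
        )
        ax.plot([1, hi], [1, hi], color="grey", lw=0.5, ls="--")
    if gene_features:
        for f in gene_features:
            ax.axvspan(f.start, f.end, color="gold", alpha=0.15)
    ax.set_xlabel("sequence A (bp)")
    ax.set_ylabel("sequence B (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
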