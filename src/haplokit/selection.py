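"""Partitioned dN/dS by the Nei-Gojobori counting method, plus distance-based
neighbor-joining of putative alleles.

NG86 conventions used here:

* potential synonymous/nonsynonymous sites per codon come from the fraction
  of the 3 possible single-nucleotide changes at each position that preserve
  the encoded amino acid; changes creating a stop codon count as
  nonsynonymous sites;
* observed differences in codons differing at >1 position are averaged over
  all minimal substitution pathways (orderings), excluding pathways that
  pass through a stop codon (if every pathway is blocked, all pathways are
  used);
* site counts are averaged over the two sequences of a pair;
* the Jukes-Cantor correction ``d = -(3/4) ln(1 - 4p/3)`` is applied.

Ratio conventions: ``dN = 0`` gives ratio 0; ``dS = 0`` with ``dN > 0`` is
undefined and excluded from medians; ``4p/3 >= 1`` is saturated and excluded.
"""

from __future__ import annotations

import functools
import itertools
import math
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError
from .io_core import MsaAlignment, translate_cds

STATUS_OK = "ok"
STATUS_ZERO_DN = "zero_dN"
STATUS_UNDEFINED_DS = "undefined_dS"
STATUS_SATURATED = "saturated"

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_BASES = "ACGT"


def _aa(codon: str) -> str:
    return translate_cds(codon)


# per-codon potential synonymous sites, cached
_SYN_SITES: dict[str, float] = {}


def _syn_sites(codon: str) -> float:
    if codon in _SYN_SITES:
        return _SYN_SITES[codon]
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in _STOPS and _aa(mutant) == aa:
                s += 1.0 / 3.0
    _SYN_SITES[codon] = s
    return s


@functools.lru_cache(maxsize=None)
def _pathway_counts(codon_i: str, codon_j: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair."""
    diff_positions = [p for p in range(3) if codon_i[p] != codon_j[p]]
    if not diff_positions:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = codon_i
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_j[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if _aa(nxt) == _aa(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        all_paths.append((syn, nonsyn))
        if not blocked:
            valid.append((syn, nonsyn))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC-corrected distance, or None when saturated (4p/3 >= 1)."""
    if p == 0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


@dataclass
class DnDsEstimate:
    id_i: str
    id_j: str
    segment: str
    n_codons: int  # codon pairs actually compared
    n_skipped: int  # gap- or stop-containing codon pairs
    Nd: float
    Sd: float
    N_sites: float
    S_sites: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    status: str
    ratio: float | None

    @property
    def included_in_median(self) -> bool:
        return self.status in (STATUS_OK, STATUS_ZERO_DN)


def _split_codons(row: str) -> list[str]:
    return [row[i : i + 3] for i in range(0, len(row), 3)]


def ng86_pair(
    codons_i: Sequence[str] | str,
    codons_j: Sequence[str] | str,
    segment_mask: Sequence[int] | None = None,
    id_i: str = "i",
    id_j: str = "j",
    segment: str = "all",
) -> DnDsEstimate:
    """NG86 dN/dS for one aligned codon sequence pair.

    ``segment_mask`` selects 0-based codon indices; codon pairs containing a
    gap, an ambiguous base, or a stop codon are skipped and counted.
    """
    if isinstance(codons_i, str):
        if len(codons_i) % 3 or len(codons_j) % 3:
            raise DomainError("codon strings must have length divisible by 3")
        codons_i = _split_codons(codons_i)
        codons_j = _split_codons(codons_j)
    if len(codons_i) != len(codons_j):
        raise DomainError("codon sequences differ in length")
    indices = range(len(codons_i)) if segment_mask is None else segment_mask

    n_codons = n_skipped = 0
    Nd = Sd = N_sites = S_sites = 0.0
    for idx in indices:
        ci, cj = codons_i[idx].upper(), codons_j[idx].upper()
        if (
            set(ci + cj) - set(_BASES)
            or ci in _STOPS
            or cj in _STOPS
        ):
            n_skipped += 1
            continue
        n_codons += 1
        si, sj = _syn_sites(ci), _syn_sites(cj)
        S_sites += (si + sj) / 2.0
        N_sites += 3.0 - (si + sj) / 2.0
        sd, nd = _pathway_counts(ci, cj)
        Sd += sd
        Nd += nd

    pN = Nd / N_sites if N_sites > 0 else 0.0
    pS = Sd / S_sites if S_sites > 0 else 0.0
    dN = jukes_cantor(pN)
    dS = jukes_cantor(pS)

    if dN == 0:  # fully conserved at nonsynonymous sites, whatever dS did
        status, ratio = STATUS_ZERO_DN, 0.0
    elif dN is None or dS is None:
        status, ratio = STATUS_SATURATED, None
    elif dS == 0:
        status, ratio = STATUS_UNDEFINED_DS, None
    else:
        status, ratio = STATUS_OK, dN / dS

    return DnDsEstimate(
        id_i=id_i, id_j=id_j, segment=segment,
        n_codons=n_codons, n_skipped=n_skipped,
        Nd=Nd, Sd=Sd, N_sites=N_sites, S_sites=S_sites,
        pN=pN, pS=pS, dN=dN, dS=dS, status=status, ratio=ratio,
    )


# ---------------------------------------------------------------------------
# segment partition and medians
# ---------------------------------------------------------------------------


@dataclass
class SegmentPartition:
    """Named, disjoint 1-based inclusive codon-index ranges."""

    segments: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, ranges in self.segments.items():
            for lo, hi in ranges:
                if lo < 1 or lo > hi:
                    raise DomainError(f"segment {name!r}: bad range {lo}-{hi}")
                span = set(range(lo, hi + 1))
                if span & seen:
                    raise DomainError(f"segment {name!r} overlaps another segment")
                seen |= span

    def mask(self, name: str, n_codons: int) -> list[int]:
        """0-based codon indices of a segment, clipped to the alignment."""
        out: list[int] = []
        for lo, hi in self.segments[name]:
            out.extend(i - 1 for i in range(lo, hi + 1) if i <= n_codons)
        return sorted(out)

    @classmethod
    def with_remainder(
        cls, named: Mapping[str, list[tuple[int, int]]], n_codons: int
    ) -> "SegmentPartition":
        """Add a 'remainder' segment covering all unassigned codons."""
        used: set[int] = set()
        for ranges in named.values():
            for lo, hi in ranges:
                used |= set(range(lo, hi + 1))
        rest = sorted(set(range(1, n_codons + 1)) - used)
        ranges: list[tuple[int, int]] = []
        for idx in rest:
            if ranges and idx == ranges[-1][1] + 1:
                ranges[-1] = (ranges[-1][0], idx)
            else:
                ranges.append((idx, idx))
        segments = {k: list(v) for k, v in named.items()}
        if ranges:
            segments["remainder"] = ranges
        return cls(segments=segments)


@dataclass
class SegmentSummary:
    per_segment: dict[str, dict]  # name -> {median, n_pairs_used, n_pairs_excluded}
    pairs: list[DnDsEstimate] = field(default_factory=list)

    def median(self, segment: str) -> float | None:
        return self.per_segment[segment]["median"]


def segment_medians(
    alignment: MsaAlignment, partition: SegmentPartition
) -> SegmentSummary:
    """Median pairwise dN/dS per named segment over all unordered row pairs."""
    if alignment.mode != "codon":
        raise DomainError("segment_medians requires a codon alignment")
    if alignment.n_rows < 2:
        raise DomainError("need at least 2 sequences")
    codon_rows = [_split_codons(r) for r in alignment.rows]
    n_codons = len(codon_rows[0])
    summary = SegmentSummary(per_segment={})
    for name in partition.segments:
        mask = partition.mask(name, n_codons)
        ratios: list[float] = []
        excluded = 0
        for i, j in itertools.combinations(range(alignment.n_rows), 2):
            est = ng86_pair(
                codon_rows[i], codon_rows[j], segment_mask=mask,
                id_i=alignment.ids[i], id_j=alignment.ids[j], segment=name,
            )
            summary.pairs.append(est)
            if est.n_codons == 0:
                excluded += 1
            elif est.included_in_median:
                ratios.append(est.ratio)
            else:
                excluded += 1
        summary.per_segment[name] = {
            "median": statistics.median(ratios) if ratios else None,
            "n_pairs_used": len(ratios),
            "n_pairs_excluded": excluded,
        }
    return summary


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


def p_distance_matrix(msa: MsaAlignment) -> tuple[list[str], np.ndarray]:
    """Pairwise proportion of differing sites over mutually non-gap columns."""
    if msa.n_rows < 2:
        raise DomainError("need at least 2 rows")
    n = msa.n_rows
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = msa.rows[i], msa.rows[j]
            comparable = diffs = 0
            for a, b in zip(ri, rj):
                if a in "-." or b in "-.":
                    continue
                comparable += 1
                if a != b:
                    diffs += 1
            if comparable == 0:
                raise DomainError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            mat[i, j] = mat[j, i] = diffs / comparable
    return list(msa.ids), mat


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class NJTree:
    root: TreeNode  # unrooted: root is the final 3-degree (or 2-degree) node
    clamped: bool = False  # any negative branch length clamped to zero

    def leaves(self) -> list[str]:
        return sorted(self.root.leaves())

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise path-length matrix between leaves."""
        # collect edges via DFS, then shortest paths on the tree graph
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}
        counter = itertools.count()

        def walk(node: TreeNode) -> int:
            nid = next(counter)
            adj.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for child, length in node.children:
                cid = walk(child)
                adj[nid].append((cid, length))
                adj[cid].append((nid, length))
            return nid

        walk(self.root)
        leaf_ids = sorted(names, key=lambda i: names[i])
        labels = [names[i] for i in leaf_ids]
        n = len(leaf_ids)
        mat = np.zeros((n, n))
        for a, src in enumerate(leaf_ids):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nbr, length in adj[node]:
                    if nbr not in dist:
                        dist[nbr] = dist[node] + length
                        stack.append(nbr)
            for b, dst in enumerate(leaf_ids):
                mat[a, b] = dist[dst]
        return labels, mat


def nj_tree(labels: Sequence[str], matrix: np.ndarray) -> NJTree:
    """Saitou-Nei neighbor joining with deterministic lexicographic tie-breaking.

    Negative branch-length estimates are clamped to zero and flagged.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if n < 3:
        raise DomainError("neighbor joining needs at least 3 taxa")
    if matrix.shape != (n, n):
        raise DomainError("matrix shape does not match label count")
    if not np.allclose(matrix, matrix.T):
        raise DomainError("distance matrix must be symmetric")
    if np.any(np.diag(matrix) != 0):
        raise DomainError("distance matrix diagonal must be zero")
    if np.any(matrix < 0):
        raise DomainError("distances must be non-negative")

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    dist: dict[frozenset, float] = {}
    active = list(labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((labels[i], labels[j]))] = matrix[i, j]

    clamped = False
    merge_counter = itertools.count(1)
    while len(active) > 3:
        m = len(active)
        r = {
            a: sum(dist[frozenset((a, b))] for b in active if b != a) for a in active
        }
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        la = 0.5 * d_ab + (r[a] - r[b]) / (2 * (m - 2))
        lb = d_ab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        new_name = f"__node{next(merge_counter)}"
        new_node = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        nodes[new_name] = new_node
        for c in active:
            if c in (a, b):
                continue
            d_new = 0.5 * (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - d_ab
            )
            dist[frozenset((new_name, c))] = max(d_new, 0.0)
        active = [c for c in active if c not in (a, b)] + [new_name]

    # final star join of the last 3 nodes
    a, b, c = active
    d_ab = dist[frozenset((a, b))]
    d_ac = dist[frozenset((a, c))]
    d_bc = dist[frozenset((b, c))]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    if min(la, lb, lc) < 0:
        clamped = True
        la, lb, lc = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return NJTree(root=root, clamped=clamped)
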