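"""In-silico restriction digest, probe hybridization, gel banding and
predicted-vs-observed band matching.

The digest scans the top strand for exact recognition-site occurrences
(palindromic sites make this lossless; non-palindromic sites are scanned on
both strands). Hybridization flags a fragment probe-positive when the best
local alignment between fragment and probe (either strand) covers at least
``min_overlap_bp`` aligned residue pairs at identity >= ``min_identity``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import Align

from .errors import ConfigError, DomainError
from .io_core import GenomicSequence, reverse_complement

# BLAST-like local scoring; the test oracle reimplements the same scheme
MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0


@dataclass(frozen=True)
class RecognitionSite:
    """A restriction enzyme recognition site with its top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if set(self.site) - set("ACGT"):
            raise ConfigError(f"site {self.site!r} must be over ACGT")
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ConfigError(
                f"cut offset {self.cut_offset} outside site of length {len(self.site)}"
            )

    @property
    def palindromic(self) -> bool:
        return self.site == reverse_complement(self.site)


TAQI = RecognitionSite(name="TaqI", site="TCGA", cut_offset=1)  # T^CGA


@dataclass(frozen=True)
class Fragment:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    probe_hit: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def fragment_id(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}"


@dataclass
class DigestResult:
    seq_id: str
    cut_positions: list[int]  # between-base coordinates (bases before the cut)
    fragments: list[Fragment]


def digest(seq: GenomicSequence, enzyme: RecognitionSite) -> DigestResult:
    """Cut a linear sequence at every exact occurrence of the recognition site.

    Overlapping occurrences are allowed; windows containing N never cut.
    Fragment lengths sum to the sequence length and there is one more
    fragment than cuts.
    """
    if not seq.residues:
        raise DomainError("cannot digest an empty sequence")
    residues = seq.residues
    sites = {enzyme.site}
    if not enzyme.palindromic:
        sites.add(reverse_complement(enzyme.site))
    cuts: set[int] = set()
    for site in sites:
        offset = enzyme.cut_offset if site == enzyme.site else len(site) - enzyme.cut_offset
        start = residues.find(site)
        while start != -1:
            cuts.add(start + offset)
            start = residues.find(site, start + 1)
    # drop degenerate cuts at the very ends (zero-length fragments)
    cut_list = sorted(c for c in cuts if 0 < c < len(residues))
    bounds = [0] + cut_list + [len(residues)]
    fragments = [
        Fragment(seq_id=seq.id, start=a + 1, end=b)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return DigestResult(seq_id=seq.id, cut_positions=cut_list, fragments=fragments)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _best_local_stats(fragment_seq: str, probe: str) -> tuple[int, int]:
    """(matches, aligned residue pairs) of the best-scoring local alignment."""
    aligner = _make_aligner()
    best_matches, best_pairs = 0, 0
    for strand_seq in (fragment_seq, reverse_complement(fragment_seq)):
        try:
            aln = aligner.align(strand_seq, probe)
        except ValueError:
            continue
        if not aln or aln.score <= 0:
            continue
        top = aln[0]
        matches = pairs = 0
        for (a0, a1), (b0, b1) in zip(*top.aligned):
            pairs += a1 - a0
            matches += sum(
                1
                for x, y in zip(strand_seq[a0:a1], probe[b0:b1])
                if x == y
            )
        if matches > best_matches:
            best_matches, best_pairs = matches, pairs
    return best_matches, best_pairs


_SEED_K = 11


def _seed_kmers(probe: str) -> set[str]:
    kmers = set()
    for strand in (probe, reverse_complement(probe)):
        for i in range(len(strand) - _SEED_K + 1):
            kmers.add(strand[i : i + _SEED_K])
    return kmers


def hybridize(
    result: DigestResult,
    seq: GenomicSequence,
    probe: str,
    min_identity: float = 0.80,
    min_overlap_bp: int = 60,
) -> DigestResult:
    """Flag probe-positive fragments by stringent local alignment on either strand.

    Fragments sharing no exact 11-mer with the probe (either strand) are
    rejected without alignment; at the stringent identity/overlap thresholds
    used for hybridization a qualifying homology without any intact 11-mer
    does not occur in practice.
    """
    if not probe:
        raise ConfigError("probe is empty")
    probe = probe.upper()
    if len(probe) < min_overlap_bp:
        raise ConfigError(
            f"probe length {len(probe)} shorter than min overlap {min_overlap_bp}"
        )
    seeds = _seed_kmers(probe)
    flagged: list[Fragment] = []
    for frag in result.fragments:
        frag_seq = seq.residues[frag.start - 1 : frag.end]
        hit = False
        if frag.length >= min_overlap_bp and _has_seed(frag_seq, seeds):
            matches, pairs = _best_local_stats(frag_seq, probe)
            hit = bool(pairs >= min_overlap_bp and matches / pairs >= min_identity)
        flagged.append(Fragment(frag.seq_id, frag.start, frag.end, probe_hit=hit))
    return DigestResult(
        seq_id=result.seq_id, cut_positions=result.cut_positions, fragments=flagged
    )


def _has_seed(fragment_seq: str, seeds: set[str]) -> bool:
    return any(
        fragment_seq[i : i + _SEED_K] in seeds
        for i in range(len(fragment_seq) - _SEED_K + 1)
    )


# ---------------------------------------------------------------------------
# gel-level banding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    size_bp: float
    members: tuple[str, ...] = ()  # fragment ids, empty for observed ladders


@dataclass
class BandPattern:
    bands: list[Band]  # sorted descending by size
    tolerance: float


def _relative_difference(a: float, b: float) -> float:
    return abs(a - b) / min(a, b)


def to_band_pattern(
    sizes_or_fragments: Sequence[Fragment] | Sequence[float],
    tolerance: float = 0.05,
) -> BandPattern:
    """Merge co-migrating sizes into bands by single-linkage at a relative
    tolerance; band size is the mean of its members."""
    items: list[tuple[float, str | None]] = []
    for x in sizes_or_fragments:
        if isinstance(x, Fragment):
            items.append((float(x.length), x.fragment_id))
        else:
            size = float(x)
            if size <= 0:
                raise DomainError(f"band size must be positive, got {size}")
            items.append((size, None))
    items.sort(key=lambda t: t[0])
    bands: list[Band] = []
    cluster: list[tuple[float, str | None]] = []
    for item in items:
        if cluster and _relative_difference(cluster[-1][0], item[0]) > tolerance:
            bands.append(_close_cluster(cluster))
            cluster = []
        cluster.append(item)
    if cluster:
        bands.append(_close_cluster(cluster))
    bands.sort(key=lambda b: -b.size_bp)
    return BandPattern(bands=bands, tolerance=tolerance)


def _close_cluster(cluster: list[tuple[float, str | None]]) -> Band:
    sizes = [s for s, _ in cluster]
    members = tuple(m for _, m in cluster if m is not None)
    return Band(size_bp=sum(sizes) / len(sizes), members=members)


@dataclass
class MatchReport:
    matches: list[tuple[Band, Band, float]] = field(default_factory=list)
    unmatched_predicted: list[Band] = field(default_factory=list)
    unmatched_observed: list[Band] = field(default_factory=list)


def match_bands(
    predicted: BandPattern, observed: BandPattern, tolerance: float = 0.05
) -> MatchReport:
    """Greedy one-to-one best-first matching of bands by relative size error.

    Ties in relative error are broken toward the larger band pair, making the
    report deterministic.
    """
    candidates = []
    for i, p in enumerate(predicted.bands):
        for j, o in enumerate(observed.bands):
            err = _relative_difference(p.size_bp, o.size_bp)
            if err <= tolerance:
                candidates.append((err, -max(p.size_bp, o.size_bp), i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_o: set[int] = set()
    report = MatchReport()
    for err, _, i, j in candidates:
        if i in used_p or j in used_o:
            continue
        used_p.add(i)
        used_o.add(j)
        report.matches.append((predicted.bands[i], observed.bands[j], err))
    report.unmatched_predicted = [
        b for i, b in enumerate(predicted.bands) if i not in used_p
    ]
    report.unmatched_observed = [
        b for j, b in enumerate(observed.bands) if j not in used_o
    ]
    return report


# ---------------------------------------------------------------------------
# TSV IO
# ---------------------------------------------------------------------------


def write_fragment_table(results: Sequence[DigestResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["seq_id", "start", "end", "length_bp", "probe_hit"])
        for res in results:
            for f in res.fragments:
                writer.writerow([f.seq_id, f.start, f.end, f.length, int(f.probe_hit)])


def write_match_report(report: MatchReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["status", "predicted_bp", "observed_bp", "relative_error"])
        for p, o, err in report.matches:
            writer.writerow(["matched", f"{p.size_bp:.1f}", f"{o.size_bp:.1f}", f"{err:.4f}"])
        for b in report.unmatched_predicted:
            writer.writerow(["unmatched_predicted", f"{b.size_bp:.1f}", "", ""])
        for b in report.unmatched_observed:
            writer.writerow(["unmatched_observed", "", f"{b.size_bp:.1f}", ""])


def read_observed_bands(path: str | Path) -> list[float]:
    """Read an observed band ladder: one size (bp) per line, header optional."""
    sizes: list[float] = []
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if not token or token.lower() in ("size", "size_bp", "bp"):
                continue
            sizes.append(float(token))
    return sorted(sizes, reverse=True)
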