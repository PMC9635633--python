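"""Synthetic repeat-dense multigene haplotypes with exact ground truth.

A generated haplotype emulates the structure of the real region: gene-family
members placed roughly every ``gene_spacing_bp``, interspersed repeats filling
a target fraction of the sequence, and multi-kilobase segmental duplications
implanted in direct or inverted orientation as full or 5'/3'-partial copies.
Every placed element is reported in a :class:`SyntheticTruth` so downstream
callers can be scored exactly.

Gene templates are fixed literal sequences (derived once from a frozen
generator at import time), so protein-identity typing of implanted loci is
deterministic. Repeat instances are unique random sequences: repeat *content*
is modeled as annotated intervals, not as homologous element families, which
keeps k-mer dot plots free of incidental anchors (realistic retroelement
sequence models are a non-goal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError
from .dotplot import BlockCopy, DuplicationBlock
from .io_core import (
    FeatureRecord,
    GenomicSequence,
    RepeatRecord,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_repeatmasker_out,
)
from .southern import TAQI, RecognitionSite, digest, hybridize, to_band_pattern

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

# codon-length (bp) of each family's template CDS, stop codon included
_FAMILY_CDS_BP = {
    "MHCY_classI": 1101,
    "YLEC": 903,
    "MHCY2B": 801,
    "LENG9L": 702,
    "ZNFY": 1203,
    "OZFL": 900,
    "rRNA": 600,
}

_N_VARIANTS = 10  # distinct templates (protein types) per family

_REPEAT_CLASS_WEIGHTS = (
    ("LTR", 0.55),
    ("LINE", 0.30),
    ("simple", 0.06),
    ("low_complexity", 0.04),
    ("tandem", 0.03),
    ("DNA_transposon", 0.02),
)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS: ATG start, stop-free body, TAA terminator."""
    n_codons = length // 3
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _build_templates() -> dict[str, list[str]]:
    """Fixed literal gene templates: one base CDS per family plus variants
    differing by a handful of nonsynonymous first-codon-position changes."""
    rng = np.random.default_rng(20220823)
    templates: dict[str, list[str]] = {}
    for family, length in _FAMILY_CDS_BP.items():
        base = _random_cds(rng, length)
        variants = [base]
        for _ in range(_N_VARIANTS - 1):
            seq = list(variants[0])
            # mutate 5 distinct internal codons at position 0 (nonsynonymous-prone)
            codon_idx = rng.choice(range(2, length // 3 - 2), size=5, replace=False)
            for ci in codon_idx:
                pos = 3 * int(ci)
                old = seq[pos]
                choices = [b for b in "ACGT" if b != old]
                new = choices[int(rng.integers(len(choices)))]
                candidate = seq[pos : pos + 3]
                candidate[0] = new
                if "".join(candidate) in _STOPS:
                    new = [b for b in choices if b != new][0]
                seq[pos] = new
            variants.append("".join(seq))
        templates[family] = variants
    return templates


GENE_TEMPLATES: dict[str, list[str]] = _build_templates()

#: probe homologous to every MHCY_classI template (shared interior window)
PROBE_SEQUENCE: str = GENE_TEMPLATES["MHCY_classI"][0][300:600]


@dataclass
class BlockSpec:
    """One segmental-duplication implant: a source segment plus extra copies."""

    length_bp: int
    n_copies: int
    orientations: list[str]  # per copy; copy 0 (the source) must be "direct"
    completeness: list[float]  # per copy in (0, 1]; copy 0 must be 1.0
    divergence: float | None = None  # per-copy substitution rate override
    target_contigs: list[int] | None = None  # contig index per extra copy

    def validate(self, n_contigs: int) -> None:
        if self.n_copies < 2:
            raise ConfigError("a block needs at least 2 copies")
        if len(self.orientations) != self.n_copies:
            raise ConfigError("orientations must list one entry per copy")
        if len(self.completeness) != self.n_copies:
            raise ConfigError("completeness must list one entry per copy")
        if self.orientations[0] != "direct" or self.completeness[0] != 1.0:
            raise ConfigError("copy 0 is the source: direct and complete")
        for o in self.orientations:
            if o not in ("direct", "inverted"):
                raise ConfigError(f"bad orientation {o!r}")
        for c in self.completeness:
            if not (0 < c <= 1):
                raise ConfigError(f"completeness {c} outside (0,1]")
        if self.target_contigs is not None:
            if len(self.target_contigs) != self.n_copies - 1:
                raise ConfigError("target_contigs lists contigs for extra copies only")
            if any(t < 0 or t >= n_contigs for t in self.target_contigs):
                raise ConfigError("target contig index out of range")


@dataclass
class HaplotypeConfig:
    n_contigs: int = 1
    contig_length_bp: int | list[int] = 200_000
    gene_spacing_bp: int = 10_000
    family_mix: dict[str, int] = field(default_factory=dict)
    repeat_fraction: float = 0.40
    block_specs: list[BlockSpec] = field(default_factory=list)
    divergence: float = 0.005
    seed: int = 0
    dropout_regions: list[tuple[str, int, int]] = field(default_factory=list)
    compute_observed_bands: bool = True

    def contig_lengths(self) -> list[int]:
        if isinstance(self.contig_length_bp, int):
            return [self.contig_length_bp] * self.n_contigs
        if len(self.contig_length_bp) != self.n_contigs:
            raise ConfigError("contig_length_bp list must match n_contigs")
        return list(self.contig_length_bp)

    def validate(self) -> None:
        if not (0 <= self.repeat_fraction <= 1):
            raise ConfigError("repeat_fraction must be in [0,1]")
        if not (0 <= self.divergence <= 0.2):
            raise ConfigError("divergence must be in [0, 0.2]")
        lengths = self.contig_lengths()
        for spec in self.block_specs:
            spec.validate(self.n_contigs)
            if spec.length_bp >= lengths[0]:
                raise ConfigError("block length must be smaller than the contig")
        for fam in self.family_mix:
            if fam not in _FAMILY_CDS_BP:
                raise ConfigError(f"unknown gene family {fam!r}")


@dataclass
class SyntheticTruth:
    features: list[FeatureRecord]
    repeats: list[RepeatRecord]
    blocks: list[DuplicationBlock]
    probe: str
    observed_bands: list[float]  # sorted descending
    dropped_regions: list[tuple[str, int, int]]
    contig_lengths: dict[str, int]
    cds_by_locus: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# contig backbone
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


class _ContigBuilder:
    def __init__(self, contig_id: str, rng: np.random.Generator):
        self.id = contig_id
        self.rng = rng
        self.parts: list[str] = []
        self.length = 0
        self.features: list[FeatureRecord] = []
        self.repeats: list[RepeatRecord] = []

    def emit(self, seq: str) -> tuple[int, int]:
        """Append sequence, return its 1-based inclusive interval."""
        start = self.length + 1
        self.parts.append(seq)
        self.length += len(seq)
        return start, self.length

    def sequence(self) -> str:
        return "".join(self.parts)


def _fill_spacer(
    builder: _ContigBuilder,
    length: int,
    repeat_state: dict,
    rng: np.random.Generator,
) -> None:
    """Fill ``length`` bp with random DNA chunks and repeat-annotated chunks,
    steering the global repeat fraction toward its target."""
    remaining = length
    target = repeat_state["target"]
    while remaining > 0:
        current_total = repeat_state["total_bp"] + 1
        fraction = repeat_state["repeat_bp"] / current_total
        want_repeat = target > 0 and fraction < target and remaining >= 80
        if want_repeat:
            rep_len = min(remaining, int(rng.integers(150, 1200)))
            cls = _pick_repeat_class(rng)
            start, end = builder.emit(_random_dna(rng, rep_len))
            builder.repeats.append(
                RepeatRecord(
                    seq_id=builder.id,
                    repeat_class=cls,
                    repeat_family=f"SYN_{cls}",
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            repeat_state["repeat_bp"] += rep_len
            repeat_state["total_bp"] += rep_len
            remaining -= rep_len
        else:
            chunk = min(remaining, int(rng.integers(200, 800)))
            builder.emit(_random_dna(rng, chunk))
            repeat_state["total_bp"] += chunk
            remaining -= chunk


def _pick_repeat_class(rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for cls, w in _REPEAT_CLASS_WEIGHTS:
        acc += w
        if u < acc:
            return cls
    return _REPEAT_CLASS_WEIGHTS[-1][0]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

_MIN_SPACER = 500


def generate_haplotype(
    config: HaplotypeConfig,
) -> tuple[list[GenomicSequence], SyntheticTruth]:
    """Build contigs plus exact truth for every placed gene, repeat and block."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = config.contig_lengths()

    # schedule genes: (family, variant) cycling through variant templates
    gene_queue: list[tuple[str, int]] = []
    for family in sorted(config.family_mix):
        for i in range(config.family_mix[family]):
            gene_queue.append((family, i % _N_VARIANTS))
    rng.shuffle(gene_queue)

    # distribute genes over contigs proportionally to length
    total_len = sum(lengths)
    shares = [round(len(gene_queue) * L / total_len) for L in lengths]
    while sum(shares) > len(gene_queue):
        shares[shares.index(max(shares))] -= 1
    while sum(shares) < len(gene_queue):
        shares[shares.index(min(shares))] += 1
    for idx, (share, L) in enumerate(zip(shares, lengths)):
        gene_bp = sum(
            _FAMILY_CDS_BP[f] for f, _ in gene_queue[:share]
        )  # upper bound estimate
        if gene_bp + share * _MIN_SPACER > L:
            raise ConfigError(
                f"contig {idx}: {share} genes (+spacers) exceed {L} bp capacity"
            )

    repeat_state = {
        "target": config.repeat_fraction,
        "repeat_bp": 0,
        "total_bp": 0,
    }
    builders: list[_ContigBuilder] = []
    cds_by_locus: dict[str, str] = {}
    locus_counter = 0
    cursor = 0
    for ci, (share, L) in enumerate(zip(shares, lengths)):
        builder = _ContigBuilder(f"contig_{ci + 1}", rng)
        my_genes = gene_queue[cursor : cursor + share]
        cursor += share
        for family, variant in my_genes:
            cds = GENE_TEMPLATES[family][variant]
            spacing = max(
                _MIN_SPACER,
                int(config.gene_spacing_bp - len(cds)
                    + rng.integers(-config.gene_spacing_bp // 5,
                                   config.gene_spacing_bp // 5 + 1)),
            )
            if builder.length + spacing + len(cds) > L:
                break
            _fill_spacer(builder, spacing, repeat_state, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = cds if strand == "+" else reverse_complement(cds)
            start, end = builder.emit(placed)
            repeat_state["total_bp"] += len(cds)
            locus_counter += 1
            locus_id = f"{family}_{locus_counter}"
            builder.features.append(
                FeatureRecord(
                    seq_id=builder.id,
                    family=family,
                    locus_id=locus_id,
                    start=start,
                    end=end,
                    strand=strand,
                    pseudogene=False,
                    full_length=True,
                )
            )
            cds_by_locus[locus_id] = cds
        if builder.length < L:
            _fill_spacer(builder, L - builder.length, repeat_state, rng)
        builders.append(builder)

    # implant segmental-duplication blocks (sources sampled from the backbone
    # of contig 1 only, and never overlapping each other)
    blocks: list[DuplicationBlock] = []
    backbone_len = builders[0].length
    reserved: list[tuple[int, int]] = []
    for bi, spec in enumerate(config.block_specs):
        blocks.append(
            _implant_block(
                spec, bi, builders, config, rng, cds_by_locus,
                backbone_len, reserved,
            )
        )

    sequences = [GenomicSequence(b.id, b.sequence()) for b in builders]
    features = [f for b in builders for f in b.features]
    repeats = [r for b in builders for r in b.repeats]

    observed: list[float] = []
    if config.compute_observed_bands:
        observed = generate_observed_bands(
            sequences, PROBE_SEQUENCE, TAQI, config.dropout_regions
        )

    truth = SyntheticTruth(
        features=features,
        repeats=repeats,
        blocks=blocks,
        probe=PROBE_SEQUENCE,
        observed_bands=observed,
        dropped_regions=list(config.dropout_regions),
        contig_lengths={s.id: len(s) for s in sequences},
        cds_by_locus=cds_by_locus,
    )
    for f in truth.features:
        if f.end > truth.contig_lengths[f.seq_id]:  # pragma: no cover - invariant
            raise DomainError(f"truth feature {f.locus_id} outside contig")
    return sequences, truth


def _implant_block(
    spec: BlockSpec,
    block_index: int,
    builders: list[_ContigBuilder],
    config: HaplotypeConfig,
    rng: np.random.Generator,
    cds_by_locus: dict[str, str],
    backbone_len: int,
    reserved: list[tuple[int, int]],
) -> DuplicationBlock:
    """Pick a source segment on contig 1 and append diverged copies."""
    src = builders[0]
    L = spec.length_bp
    if backbone_len <= L + 4000:
        raise ConfigError("contig 1 too short for the requested block")
    # place the source inside a free gap of the backbone (2 kb insulation)
    margin = 2000
    bounds = sorted((lo - margin, hi + margin) for lo, hi in reserved)
    free: list[tuple[int, int]] = []
    cursor = 1000
    for lo, hi in bounds + [(backbone_len - 1000, backbone_len)]:
        if lo - cursor >= L:
            free.append((cursor, lo))
        cursor = max(cursor, hi)
    if not free:
        raise ConfigError("could not place block source without overlap")
    gap = free[int(rng.integers(len(free)))]
    start0 = int(rng.integers(gap[0], gap[1] - L + 1))
    reserved.append((start0, start0 + L))
    source = src.sequence()[start0 : start0 + L]
    src_interval = (start0 + 1, start0 + L)
    divergence = config.divergence if spec.divergence is None else spec.divergence

    copies = [
        BlockCopy(
            seq_id=src.id, interval=src_interval, orientation="direct",
            completeness=1.0,
        )
    ]
    targets = spec.target_contigs or [
        (block_index + 1 + i) % len(builders) for i in range(spec.n_copies - 1)
    ]
    for copy_i in range(1, spec.n_copies):
        orientation = spec.orientations[copy_i]
        completeness = spec.completeness[copy_i]
        keep = max(1, int(round(L * completeness)))
        five_prime = bool(rng.random() < 0.5) if completeness < 1.0 else True
        segment = source[:keep] if five_prime else source[L - keep :]
        offset_in_source = 0 if five_prime else L - keep
        segment = _mutate(segment, divergence, rng)
        if orientation == "inverted":
            segment = reverse_complement(segment)
        target = builders[targets[copy_i - 1]]
        target.emit(_random_dna(rng, 2000))  # insulating spacer
        start, end = target.emit(segment)
        copies.append(
            BlockCopy(
                seq_id=target.id, interval=(start, end), orientation=orientation,
                completeness=keep / L,
            )
        )
        _duplicate_annotations(
            src, src_interval, offset_in_source, keep, orientation,
            target, start, copy_i, block_index, cds_by_locus, divergence,
        )
    return DuplicationBlock(
        block_id=f"truth_block_{block_index + 1}",
        archetype_length_bp=L,
        copies=copies,
    )


def _duplicate_annotations(
    src: _ContigBuilder,
    src_interval: tuple[int, int],
    offset_in_source: int,
    keep: int,
    orientation: str,
    target: _ContigBuilder,
    target_start: int,
    copy_i: int,
    block_index: int,
    cds_by_locus: dict[str, str],
    divergence: float,
) -> None:
    """Project features/repeats wholly inside the copied window onto the copy."""
    win_lo = src_interval[0] + offset_in_source
    win_hi = win_lo + keep - 1

    def project(start: int, end: int, strand: str) -> tuple[int, int, str]:
        rel_lo, rel_hi = start - win_lo, end - win_lo
        if orientation == "inverted":
            new_lo = target_start + (keep - 1 - rel_hi)
            new_hi = target_start + (keep - 1 - rel_lo)
            new_strand = "-" if strand == "+" else "+"
        else:
            new_lo, new_hi = target_start + rel_lo, target_start + rel_hi
            new_strand = strand
        return new_lo, new_hi, new_strand

    for f in src.features:
        if f.start >= win_lo and f.end <= win_hi:
            lo, hi, strand = project(f.start, f.end, f.strand)
            new_id = f"{f.locus_id}_b{block_index + 1}c{copy_i + 1}"
            target.features.append(
                FeatureRecord(
                    seq_id=target.id, family=f.family, locus_id=new_id,
                    start=lo, end=hi, strand=strand, pseudogene=f.pseudogene,
                    full_length=f.full_length and divergence == 0,
                )
            )
            if f.locus_id in cds_by_locus and divergence == 0:
                cds_by_locus[new_id] = cds_by_locus[f.locus_id]
    for r in src.repeats:
        if r.start >= win_lo and r.end <= win_hi:
            lo, hi, strand = project(r.start, r.end, r.strand)
            target.repeats.append(
                RepeatRecord(
                    seq_id=target.id, repeat_class=r.repeat_class,
                    repeat_family=r.repeat_family, start=lo, end=hi, strand=strand,
                )
            )


# ---------------------------------------------------------------------------
# observed bands and dropout
# ---------------------------------------------------------------------------


def generate_observed_bands(
    sequences: Sequence[GenomicSequence],
    probe: str,
    enzyme: RecognitionSite = TAQI,
    dropout: Sequence[tuple[str, int, int]] = (),
) -> list[float]:
    """Gel-level band ladder from digesting the FULL truth sequences.

    The digest+hybridization runs on the complete contigs (dropout regions
    included), so bands whose fragments lie in dropout regions are observed
    here but cannot be predicted from the truncated assembly downstream.
    """
    sizes: list[float] = []
    for seq in sequences:
        result = hybridize(digest(seq, enzyme), seq, probe)
        sizes.extend(f.length for f in result.fragments if f.probe_hit)
    if not sizes:
        return []
    pattern = to_band_pattern(sizes)
    _ = dropout  # dropout shapes the *predicted* side via truncate_sequences
    return [b.size_bp for b in pattern.bands]


def truncate_sequences(
    sequences: Sequence[GenomicSequence],
    dropout: Sequence[tuple[str, int, int]],
) -> list[GenomicSequence]:
    """Remove dropout intervals (1-based inclusive), emulating regions never
    captured in clones; flanks are joined."""
    out: list[GenomicSequence] = []
    for seq in sequences:
        cuts = sorted(
            [(s, e) for sid, s, e in dropout if sid == seq.id], reverse=True
        )
        residues = seq.residues
        for s, e in cuts:
            if not (1 <= s <= e <= len(residues)):
                raise DomainError(f"dropout {s}-{e} outside {seq.id}")
            residues = residues[: s - 1] + residues[e:]
        if residues:
            out.append(GenomicSequence(seq.id, residues))
    return out


# ---------------------------------------------------------------------------
# controlled-polymorphism alignments
# ---------------------------------------------------------------------------

_INVARIANT_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def generate_class1_alignment(
    n_rows: int,
    width: int,
    polymorphic_cols: dict[int, dict[str, float]] | None = None,
    seed: int = 0,
) -> "MsaAlignment":
    """Protein alignment with exact per-column residue counts.

    ``polymorphic_cols`` maps 1-based columns to residue->frequency specs
    (frequencies summing to 1; ``freq * n_rows`` assignments are made by
    largest-remainder rounding so the realized counts are deterministic).
    Unlisted columns are invariant.
    """
    from .io_core import MsaAlignment

    polymorphic_cols = polymorphic_cols or {}
    rng = np.random.default_rng(seed)
    for col in polymorphic_cols:
        if not (1 <= col <= width):
            raise ConfigError(f"column {col} outside width {width}")
    grid = [
        [_INVARIANT_RESIDUES[j % len(_INVARIANT_RESIDUES)] for j in range(width)]
        for _ in range(n_rows)
    ]
    for col, spec in polymorphic_cols.items():
        total = sum(spec.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"column {col}: frequencies sum to {total}, not 1")
        residues = sorted(spec)
        raw = [spec[r] * n_rows for r in residues]
        counts = [int(x) for x in raw]
        remainders = sorted(
            range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True
        )
        for i in remainders[: n_rows - sum(counts)]:
            counts[i] += 1
        column = [r for r, c in zip(residues, counts) for _ in range(c)]
        rng.shuffle(column)
        for row_i in range(n_rows):
            grid[row_i][col - 1] = column[row_i]
    return MsaAlignment(
        ids=[f"row_{i + 1}" for i in range(n_rows)],
        rows=["".join(r) for r in grid],
        mode="protein",
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "contig_lengths": truth.contig_lengths,
        "probe": truth.probe,
        "observed_bands": truth.observed_bands,
        "dropped_regions": [list(d) for d in truth.dropped_regions],
        "features": [
            {
                "seq_id": f.seq_id, "family": f.family, "locus_id": f.locus_id,
                "start": f.start, "end": f.end, "strand": f.strand,
                "pseudogene": f.pseudogene, "full_length": f.full_length,
            }
            for f in truth.features
        ],
        "repeats": [
            {
                "seq_id": r.seq_id, "repeat_class": r.repeat_class,
                "repeat_family": r.repeat_family, "start": r.start,
                "end": r.end, "strand": r.strand,
            }
            for r in truth.repeats
        ],
        "blocks": [
            {
                "block_id": b.block_id,
                "archetype_length_bp": b.archetype_length_bp,
                "copies": [
                    {
                        "seq_id": c.seq_id, "start": c.interval[0],
                        "end": c.interval[1], "orientation": c.orientation,
                        "completeness": c.completeness,
                    }
                    for c in b.copies
                ],
            }
            for b in truth.blocks
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_outputs(
    outdir: str | Path,
    sequences: Sequence[GenomicSequence],
    truth: SyntheticTruth,
) -> None:
    """Write contigs.fa, probe.fa, features.gff3, repeats.out, bands.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sequences, outdir / "contigs.fa")
    write_fasta([GenomicSequence("probe", truth.probe)], outdir / "probe.fa")
    write_gff3(truth.features, outdir / "features.gff3")
    write_repeatmasker_out(truth.repeats, outdir / "repeats.out")
    with open(outdir / "observed_bands.tsv", "w") as fh:
        fh.write("size_bp\n")
        for size in truth.observed_bands:
            fh.write(f"{size:.1f}\n")
    write_truth_json(truth, outdir / "truth.json")
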