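"""Readers/writers for the external formats and the shared sequence/coordinate model.

Coordinates are 1-based inclusive everywhere (GFF3 convention). The GFF3
dialect used for gene annotations carries ``family``, ``pseudogene``,
``type_label`` and ``full_length`` attribute keys; unknown families are
mapped to ``"other"`` with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

GENE_FAMILIES = (
    "MHCY_classI",
    "YLEC",
    "MHCY2B",
    "LENG9L",
    "ZNFY",
    "OZFL",
    "rRNA",
    "other",
)

REPEAT_CLASSES = (
    "LTR",
    "LINE",
    "DNA_transposon",
    "tandem",
    "small_RNA",
    "satellite",
    "simple",
    "low_complexity",
)

_DNA_ALPHABET = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicSequence:
    """A linear DNA sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise DomainError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated locus (1-based inclusive coordinates)."""

    seq_id: str
    family: str
    locus_id: str
    start: int
    end: int
    strand: str = "+"
    pseudogene: bool = False
    type_label: str | None = None
    full_length: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature {self.locus_id!r}: invalid span {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.locus_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepeatRecord:
    """One masked repeat interval (1-based inclusive coordinates)."""

    seq_id: str
    repeat_class: str
    repeat_family: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"repeat {self.repeat_family!r}: start {self.start} > end {self.end}"
            )
        if self.repeat_class not in REPEAT_CLASSES and self.repeat_class != "other":
            raise FormatError(f"unknown repeat class {self.repeat_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MsaAlignment:
    """A rectangular multiple alignment (protein or codon rows)."""

    ids: list[str]
    rows: list[str]
    mode: str = "protein"
    groups: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in number")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(widths)}")
        if self.mode == "codon" and self.rows and len(self.rows[0]) % 3 != 0:
            raise FormatError(
                f"codon alignment width {len(self.rows[0])} not divisible by 3"
            )
        if not self.groups:
            self.groups = [None] * len(self.ids)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset(self, indices: Sequence[int]) -> "MsaAlignment":
        return MsaAlignment(
            ids=[self.ids[i] for i in indices],
            rows=[self.rows[i] for i in indices],
            mode=self.mode,
            groups=[self.groups[i] for i in indices],
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a (possibly empty) multi-FASTA file into GenomicSequences.

    Residues are upper-cased; record order is preserved.
    """
    out: list[GenomicSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(GenomicSequence(id=rec.id, residues=str(rec.seq).upper()))
    return out


def write_fasta(sequences: Iterable[GenomicSequence], path: str | Path) -> None:
    """Write sequences as multi-FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (documented dialect: attributes family, pseudogene, type_label, full_length)
# ---------------------------------------------------------------------------


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF3 attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Read locus annotations from a GFF3 file.

    Coordinates are kept 1-based inclusive exactly as stored. Features with
    an unknown ``family`` attribute are mapped to ``"other"`` with a warning.
    """
    out: list[FeatureRecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seq_id, _source, _ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            attrs = _parse_gff_attributes(attr_s)
            locus_id = attrs.get("ID") or attrs.get("locus_id")
            if locus_id is None:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            if locus_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate locus_id {locus_id!r}")
            seen_ids.add(locus_id)
            family = attrs.get("family", "other")
            if family not in GENE_FAMILIES:
                logger.warning(
                    "%s:%d: unknown family %r mapped to 'other'", path, lineno, family
                )
                family = "other"
            out.append(
                FeatureRecord(
                    seq_id=seq_id,
                    family=family,
                    locus_id=locus_id,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else "+",
                    pseudogene=attrs.get("pseudogene", "false").lower() == "true",
                    type_label=attrs.get("type_label") or None,
                    full_length=attrs.get("full_length", "false").lower() == "true",
                )
            )
    return out


def write_gff3(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.locus_id}", f"family={f.family}",
                     f"pseudogene={'true' if f.pseudogene else 'false'}",
                     f"full_length={'true' if f.full_length else 'false'}"]
            if f.type_label:
                attrs.append(f"type_label={f.type_label}")
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        "haplokit",
                        "gene",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

# class/family column prefix -> closed vocabulary
_RM_CLASS_PREFIXES = (
    ("LTR", "LTR"),
    ("LINE", "LINE"),
    ("SINE", "other"),
    ("DNA", "DNA_transposon"),
    ("RC", "DNA_transposon"),
    ("Simple_repeat", "simple"),
    ("Low_complexity", "low_complexity"),
    ("Satellite", "satellite"),
    ("tRNA", "small_RNA"),
    ("snRNA", "small_RNA"),
    ("srpRNA", "small_RNA"),
    ("rRNA", "small_RNA"),
    ("scRNA", "small_RNA"),
    ("Tandem", "tandem"),
)


def classify_repeat(class_family: str) -> str:
    """Map a RepeatMasker class/family string onto the closed class vocabulary."""
    for prefix, mapped in _RM_CLASS_PREFIXES:
        if class_family == prefix or class_family.startswith(prefix + "/"):
            return mapped
    # ERV* family names occasionally appear bare in the class column
    if class_family.startswith("ERV"):
        return "LTR"
    return "other"


def read_repeatmasker_out(path: str | Path) -> list[RepeatRecord]:
    """Read a RepeatMasker ``.out`` table (3 header lines, whitespace columns).

    Rows whose class string is unknown are kept in a logged "other" bucket
    that repeat summaries exclude from the named classes.
    """
    out: list[RepeatRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        # header lines start with the column banner or underline
        if stripped.startswith(("SW", "score", "bit")):
            continue
        cols = stripped.split()
        if len(cols) < 11:
            raise FormatError(f"{path}:{lineno}: unparseable RepeatMasker row")
        try:
            seq_id = cols[4]
            start, end = int(cols[5]), int(cols[6])
            strand = "+" if cols[8] == "+" else "-"
            family = cols[9]
            class_family = cols[10]
        except (ValueError, IndexError):
            raise FormatError(f"{path}:{lineno}: unparseable RepeatMasker row") from None
        repeat_class = classify_repeat(class_family)
        if repeat_class == "other":
            logger.warning("%s:%d: class %r bucketed as 'other'", path, lineno, class_family)
        out.append(
            RepeatRecord(
                seq_id=seq_id,
                repeat_class=repeat_class,
                repeat_family=family,
                start=start,
                end=end,
                strand=strand,
            )
        )
    logger.info("read %d repeat records from %s", len(out), path)
    return out


def write_repeatmasker_out(repeats: Iterable[RepeatRecord], path: str | Path) -> None:
    """Write repeats in the RepeatMasker .out column layout (round-trippable)."""
    # invert the classification for a representative class/family string
    class_for = {
        "LTR": "LTR/ERV1",
        "LINE": "LINE/CR1",
        "DNA_transposon": "DNA/hAT-Charlie",
        "tandem": "Tandem",
        "small_RNA": "tRNA",
        "satellite": "Satellite",
        "simple": "Simple_repeat",
        "low_complexity": "Low_complexity",
        "other": "Unknown",
    }
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID\n"
            "\n"
        )
        for i, r in enumerate(repeats, start=1):
            fh.write(
                f"  225  10.0  0.0  0.0  {r.seq_id} {r.start} {r.end} (0) "
                f"{'+' if r.strand == '+' else 'C'} {r.repeat_family} "
                f"{class_for[r.repeat_class]} 1 {r.length} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# aligned FASTA
# ---------------------------------------------------------------------------


def read_msa(path: str | Path, mode: str = "protein") -> MsaAlignment:
    """Read an aligned FASTA into an MsaAlignment.

    Headers of the form ``>id|group=NAME`` populate per-row group labels.
    """
    if mode not in ("protein", "codon"):
        raise ValueError(f"mode must be 'protein' or 'codon', got {mode!r}")
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    ids, rows, groups = [], [], []
    for rec in aln:
        rid = rec.id
        group = None
        if "|group=" in rec.description:
            group = rec.description.split("|group=", 1)[1].split()[0]
            rid = rid.split("|group=", 1)[0]
        ids.append(rid)
        rows.append(str(rec.seq).upper())
        groups.append(group)
    return MsaAlignment(ids=ids, rows=rows, mode=mode, groups=groups)


def write_msa(msa: MsaAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row, group in zip(msa.ids, msa.rows, msa.groups):
            header = rid if group is None else f"{rid}|group={group}"
            fh.write(f">{header}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def translate_cds(dna: str, frame: int = 1) -> str:
    """Translate a CDS with the standard code.

    Internal stop codons are preserved as ``'*'`` (they matter for pseudogene
    detection); codons containing non-ACGT characters translate to ``'X'``.
    """
    if frame != 1:
        raise DomainError("only frame 1 is supported")
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise DomainError(f"CDS length {len(dna)} not divisible by 3")
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if set(codon) - set("ACGT"):
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())
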