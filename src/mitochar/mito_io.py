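"""Data model and I/O for circular mitogenomes and their annotations.

Coordinates are 1-based inclusive throughout, following the GenBank and
printed-table convention. A feature that spans the origin of the circle is
expressed with ``end > genome_length`` (e.g. a control region printed as
14,999-15,370 on a 15,369 bp genome); the wrap is resolved only when a
sequence is extracted.

Strands are called *major* (the strand the genome sequence is reported on,
"F" in feature tables) and *minor* ("R"); the heavy/light nomenclature is
deliberately avoided.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mitochar.errors import CoordinateError, ParseError, ValidationError

__all__ = [
    "FeatureClass",
    "Strand",
    "Mitogenome",
    "GeneFeature",
    "AnnotationTable",
    "Violation",
    "GENE_VOCABULARY",
    "normalize_gene_name",
    "read_genome",
    "write_genome",
    "read_feature_table",
    "write_feature_table",
    "extract_gene_sequence",
    "reverse_complement",
    "validate_annotation",
]


class FeatureClass(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"


class Strand(str, Enum):
    MAJOR = "major"  # "F" in feature tables
    MINOR = "minor"  # "R"


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The 37 canonical mitochondrial gene names plus the control region.
GENE_VOCABULARY = frozenset(
    [f"nad{i}" for i in range(1, 7)]
    + ["nad4L", "cox1", "cox2", "cox3", "atp6", "atp8", "cob", "rrnL", "rrnS"]
    + [
        "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG",
        "trnH", "trnI", "trnK", "trnM", "trnF", "trnP", "trnT", "trnW",
        "trnY", "trnV", "trnL1", "trnL2", "trnS1", "trnS2",
    ]
    + ["control_region"]
)

# Aliases seen in GenBank records and legacy tables, applied on read.
_ALIASES = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd5": "nad5", "nd6": "nad6", "nd4l": "nad4L", "nad4l": "nad4L",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "cytb": "cob", "cob": "cob", "atpase6": "atp6", "atpase8": "atp8",
    "16s": "rrnL", "l-rrna": "rrnL", "rrn16": "rrnL", "lsu": "rrnL",
    "12s": "rrnS", "s-rrna": "rrnS", "rrn12": "rrnS", "ssu": "rrnS",
    "a+t-rich region": "control_region", "at-rich region": "control_region",
    "d-loop": "control_region", "control region": "control_region",
    "trnl1(cun)": "trnL1", "trnl2(uur)": "trnL2",
    "trns1(agn)": "trnS1", "trns2(ucn)": "trnS2",
    "trnl(cun)": "trnL1", "trnl(uur)": "trnL2",
    "trns(agn)": "trnS1", "trns(ucn)": "trnS2",
}

_AA3_TO_TRN = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "glu": "E", "gln": "Q", "gly": "G", "his": "H", "ile": "I",
    "lys": "K", "met": "M", "phe": "F", "pro": "P", "thr": "T",
    "trp": "W", "tyr": "Y", "val": "V",
}


def normalize_gene_name(raw: str) -> tuple[str, bool]:
    """Map a raw gene label to the canonical vocabulary.

    Returns ``(name, recognized)``; unrecognized labels are passed through
    unchanged with ``recognized=False``.
    """
    label = raw.strip()
    key = label.lower().replace("*", "").replace("_", "").strip()
    key = re.sub(r"\s+", " ", key)
    if key in _ALIASES:
        return _ALIASES[key], True
    m = re.fullmatch(r"trna-(\w{3})(?:\s*\(\w{3}\))?", key)
    if m and m.group(1) in _AA3_TO_TRN:
        return "trn" + _AA3_TO_TRN[m.group(1)], True
    compact = key.replace(" ", "")
    if compact in _ALIASES:
        return _ALIASES[compact], True
    for cand in (label, compact):
        if cand in GENE_VOCABULARY:
            return cand, True
    # case-insensitive fallback against the vocabulary
    lower_map = {g.lower(): g for g in GENE_VOCABULARY}
    if compact.lower() in lower_map:
        return lower_map[compact.lower()], True
    return label, False


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Mitogenome:
    """A circular (or linear) mitochondrial genome sequence."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError("genome sequence must be nonempty")
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValidationError(f"illegal characters in genome: {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature in 1-based inclusive coordinates.

    ``declared_size`` and ``declared_intergenic`` preserve a source table's
    printed values verbatim, even when they disagree with the coordinates;
    :func:`validate_annotation` reports such disagreements.
    """

    name: str
    cls: FeatureClass
    strand: Strand
    start: int
    end: int
    anticodon: Optional[str] = None
    declared_size: Optional[int] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    declared_intergenic: Optional[int] = None
    recognized: bool = True

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise CoordinateError(
                f"{self.name}: end ({self.end}) < start ({self.start}); "
                "origin-spanning features use end > genome length instead"
            )
        if self.cls is FeatureClass.TRNA and not self.anticodon:
            raise ValidationError(f"{self.name}: tRNA feature requires an anticodon")

    @property
    def span(self) -> int:
        """Feature length in bp implied by the coordinates."""
        return self.end - self.start + 1

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class AnnotationTable:
    """Ordered feature list for one genome (the in-memory feature table)."""

    features: list[GeneFeature]
    genome_length: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValidationError("genome_length must be positive")
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate gene names: {sorted(dupes)}")
        starts = [(f.start, f.end) for f in self.features]
        if starts != sorted(starts):
            raise ValidationError("features must be ordered by (start, end)")
        n_control = sum(1 for f in self.features if f.cls is FeatureClass.CONTROL)
        if n_control > 1:
            raise ValidationError("at most one control-region feature allowed")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, cls: FeatureClass) -> list[GeneFeature]:
        return [f for f in self.features if f.cls is cls]

    def census(self) -> dict[FeatureClass, int]:
        out = {c: 0 for c in FeatureClass}
        for f in self.features:
            out[f.cls] += 1
        return out


@dataclass(frozen=True)
class Violation:
    """One problem found by :func:`validate_annotation` (reported, not raised)."""

    kind: str
    feature: Optional[str]
    message: str


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: Union[str, Path], circular: bool = True) -> Mitogenome:
    """Read a single-record FASTA file into a :class:`Mitogenome`."""
    try:
        record = SeqIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return Mitogenome(id=record.id, seq=str(record.seq), circular=circular)


def write_genome(genome: Mitogenome, path: Union[str, Path]) -> None:
    record = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    SeqIO.write([record], str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV dialect

TSV_COLUMNS = [
    "gene", "class", "direction", "start", "end", "size",
    "anticodon", "start_codon", "stop_codon", "intergenic",
]

_CLS_FROM_NAME_PCG = {
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cob",
}


def _infer_class(name: str) -> FeatureClass:
    if name in _CLS_FROM_NAME_PCG:
        return FeatureClass.PCG
    if name.startswith("trn"):
        return FeatureClass.TRNA
    if name.startswith("rrn"):
        return FeatureClass.RRNA
    if name == "control_region":
        return FeatureClass.CONTROL
    return FeatureClass.PCG


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value if value not in ("", "-", "—", "None", "NA", "*") else None


def _read_tsv(path: Path, genome_length: Optional[int]) -> AnnotationTable:
    features: list[GeneFeature] = []
    header: Optional[list[str]] = None
    with open(path, newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.search(r"genome_length\s*=\s*(\d+)", line)
                if m and genome_length is None:
                    genome_length = int(m.group(1))
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip().lower() for c in cells]
                missing = {"gene", "direction", "start", "end"} - set(header)
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: missing required columns {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, cells))
            try:
                start = int(row["start"].replace(",", ""))
                end = int(row["end"].replace(",", ""))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed coordinates: {exc}") from exc
            name, recognized = normalize_gene_name(row["gene"])
            direction = row.get("direction", "F").strip() or "F"
            strand = Strand.MINOR if direction.upper() in ("R", "-", "MINOR") else Strand.MAJOR
            cls_raw = _opt(row.get("class", "") or "")
            if cls_raw:
                try:
                    cls = FeatureClass(cls_raw)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: unknown class {cls_raw!r}") from exc
            else:
                cls = _infer_class(name)
            size = _opt(row.get("size", "") or "")
            inter = _opt(row.get("intergenic", "") or "")
            try:
                features.append(
                    GeneFeature(
                        name=name,
                        cls=cls,
                        strand=strand,
                        start=start,
                        end=end,
                        anticodon=_opt(row.get("anticodon", "") or ""),
                        declared_size=int(size.replace(",", "")) if size else None,
                        start_codon=_opt(row.get("start_codon", "") or ""),
                        stop_codon=_opt(row.get("stop_codon", "") or ""),
                        declared_intergenic=int(inter) if inter is not None else None,
                        recognized=recognized,
                    )
                )
            except (CoordinateError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if header is None:
        raise ParseError(f"{path}: empty feature table")
    if not features:
        raise ParseError(f"{path}: no feature rows")
    if genome_length is None:
        genome_length = max(f.end for f in features)
    features.sort(key=lambda f: (f.start, f.end))
    return AnnotationTable(features=features, genome_length=genome_length, source=str(path))


def _write_tsv(table: AnnotationTable, path: Path) -> None:
    with open(path, "w", newline="") as handle:
        handle.write(f"#genome_length={table.genome_length}\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for f in table.features:
            writer.writerow(
                [
                    f.name,
                    f.cls.value,
                    "R" if f.strand is Strand.MINOR else "F",
                    f.start,
                    f.end,
                    "" if f.declared_size is None else f.declared_size,
                    f.anticodon or "",
                    f.start_codon or "",
                    f.stop_codon or "",
                    "" if f.declared_intergenic is None else f.declared_intergenic,
                ]
            )


# ---------------------------------------------------------------------------
# GenBank flat-file subset

_GB_CLASS = {
    FeatureClass.PCG: "CDS",
    FeatureClass.TRNA: "tRNA",
    FeatureClass.RRNA: "rRNA",
    FeatureClass.CONTROL: "misc_feature",
}
_GB_CLASS_INV = {
    "CDS": FeatureClass.PCG,
    "tRNA": FeatureClass.TRNA,
    "rRNA": FeatureClass.RRNA,
    "misc_feature": FeatureClass.CONTROL,
    "D-loop": FeatureClass.CONTROL,
}


def _read_genbank(path: Path) -> AnnotationTable:
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    genome_length = len(record.seq)
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _GB_CLASS_INV:
            continue
        cls = _GB_CLASS_INV[feat.type]
        loc = feat.location
        if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
            # origin-spanning join(a..L,1..b) -> end expressed past the origin
            first, second = loc.parts
            start = int(first.start) + 1
            end = genome_length + int(second.end)
        else:
            start = int(loc.start) + 1
            end = int(loc.end)
        strand = Strand.MINOR if loc.strand == -1 else Strand.MAJOR
        quals = feat.qualifiers
        raw_name = (quals.get("gene") or quals.get("product") or ["?"])[0]
        name, recognized = normalize_gene_name(raw_name)
        extras: dict[str, str] = {}
        for note in quals.get("note", []):
            for part in note.split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    extras[k.strip()] = v.strip()
        anticodon = (quals.get("anticodon") or [extras.get("anticodon", "")])[0] or None
        size = extras.get("declared_size")
        inter = extras.get("intergenic")
        features.append(
            GeneFeature(
                name=name,
                cls=cls,
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
                declared_size=int(size) if size else None,
                start_codon=(quals.get("codon_start_triplet") or [extras.get("start_codon")])[0],
                stop_codon=extras.get("stop_codon"),
                declared_intergenic=int(inter) if inter not in (None, "") else None,
                recognized=recognized,
            )
        )
    if not features:
        raise ParseError(f"{path}: no parseable FEATURES entries")
    features.sort(key=lambda f: (f.start, f.end))
    return AnnotationTable(features=features, genome_length=genome_length, source=str(path))


def _write_genbank(table: AnnotationTable, path: Path, genome: Optional[Mitogenome]) -> None:
    if genome is None:
        seq = Seq("N" * table.genome_length)
        name = "mitogenome"
    else:
        if genome.length != table.genome_length:
            raise ValidationError(
                f"genome length {genome.length} != table genome_length {table.genome_length}"
            )
        seq = Seq(genome.seq)
        name = genome.id
    record = SeqRecord(seq, id=name, name=name[:16], description="mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    L = table.genome_length
    for f in table.features:
        strand = -1 if f.strand is Strand.MINOR else 1
        if f.end > L:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, L, strand=strand),
                    SimpleLocation(0, f.end - L, strand=strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        notes = []
        if f.anticodon:
            notes.append(f"anticodon={f.anticodon}")
        if f.declared_size is not None:
            notes.append(f"declared_size={f.declared_size}")
        if f.start_codon:
            notes.append(f"start_codon={f.start_codon}")
        if f.stop_codon:
            notes.append(f"stop_codon={f.stop_codon}")
        if f.declared_intergenic is not None:
            notes.append(f"intergenic={f.declared_intergenic}")
        if notes:
            quals["note"] = ["; ".join(notes)]
        record.features.append(SeqFeature(loc, type=_GB_CLASS[f.cls], qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


def read_feature_table(
    path: Union[str, Path],
    dialect: str = "tsv",
    genome_length: Optional[int] = None,
) -> AnnotationTable:
    """Read an annotation table from a TSV or GenBank-flat-file subset.

    For the TSV dialect the genome length may be given as an argument, as a
    ``#genome_length=N`` header comment, or inferred from the largest end
    coordinate (in that order of precedence).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if dialect == "tsv":
        return _read_tsv(path, genome_length)
    if dialect == "genbank":
        return _read_genbank(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_feature_table(
    table: AnnotationTable,
    path: Union[str, Path],
    dialect: str = "tsv",
    genome: Optional[Mitogenome] = None,
) -> None:
    path = Path(path)
    if dialect == "tsv":
        _write_tsv(table, path)
    elif dialect == "genbank":
        _write_genbank(table, path, genome)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Coordinate arithmetic


def extract_gene_sequence(genome: Mitogenome, feature: GeneFeature) -> str:
    """Return the gene-strand (sense) sequence of ``feature``.

    The major-strand slice ``[start..end]`` is taken 1-based inclusive,
    wrapping through position 1 when ``end`` exceeds the genome length on a
    circular genome; minor-strand features are reverse complemented.
    """
    L = genome.length
    if feature.start > L:
        raise CoordinateError(f"{feature.name}: start {feature.start} > genome length {L}")
    if feature.end > L:
        if not genome.circular:
            raise CoordinateError(
                f"{feature.name}: end {feature.end} exceeds length {L} of a non-circular genome"
            )
        if feature.end - L > L:
            raise CoordinateError(f"{feature.name}: feature wraps more than once")
        piece = genome.seq[feature.start - 1 :] + genome.seq[: feature.end - L]
    else:
        piece = genome.seq[feature.start - 1 : feature.end]
    if feature.strand is Strand.MINOR:
        piece = reverse_complement(piece)
    return piece


_EXPECTED_CENSUS = {
    FeatureClass.PCG: 13,
    FeatureClass.TRNA: 22,
    FeatureClass.RRNA: 2,
    FeatureClass.CONTROL: 1,
}


def validate_annotation(
    table: AnnotationTable, circular: bool = True
) -> list[Violation]:
    """Report structural problems in an annotation table.

    Returns an empty list for a clean table. All problems are reported, not
    raised: size/coordinate disagreements, features running past the genome
    end without the circular flag, origin-spanning features that collide with
    the first feature, deviations from the canonical 13/22/2/1 gene census,
    and unrecognized gene names.
    """
    violations: list[Violation] = []
    L = table.genome_length
    for f in table.features:
        if f.declared_size is not None and f.declared_size != f.span:
            violations.append(
                Violation(
                    kind="size_mismatch",
                    feature=f.name,
                    message=(
                        f"coordinates {f.start}-{f.end} imply {f.span} bp "
                        f"but declared size is {f.declared_size}"
                    ),
                )
            )
        if f.end > L:
            if not circular:
                violations.append(
                    Violation(
                        kind="out_of_bounds",
                        feature=f.name,
                        message=f"end {f.end} exceeds genome length {L} (genome not circular)",
                    )
                )
            else:
                wrapped_end = f.end - L
                first = table.features[0]
                if first is not f and first.start <= wrapped_end:
                    violations.append(
                        Violation(
                            kind="origin_overlap",
                            feature=f.name,
                            message=(
                                f"wraps the origin to position {wrapped_end} and "
                                f"collides with {first.name} (starts at {first.start})"
                            ),
                        )
                    )
        if not f.recognized:
            violations.append(
                Violation(kind="unknown_name", feature=f.name, message="gene name not in vocabulary")
            )
    census = table.census()
    for cls, expected in _EXPECTED_CENSUS.items():
        if census[cls] != expected:
            violations.append(
                Violation(
                    kind="census",
                    feature=None,
                    message=f"expected {expected} {cls.value} features, found {census[cls]}",
                )
            )
    return violations
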