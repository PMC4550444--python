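"""Base composition, A+T content and strand skews.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed from
counts or, equivalently, from percentages of the same sequence. Positive AT
skew means an excess of A over T on the strand examined. Percentages are
computed over non-N bases; N contributes to length but never to a
denominator. Rounding (half-up, 2 decimals for percentages and 3 for skews)
happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from mitochar.errors import MitocharError
from mitochar.mito_io import (
    AnnotationTable,
    FeatureClass,
    Mitogenome,
    Strand,
    extract_gene_sequence,
)

__all__ = [
    "CompositionStats",
    "base_composition",
    "skew",
    "partition_composition",
    "coverage_fraction",
    "round_half_up",
]

PARTITIONS = ("whole", "PCG", "tRNA", "rRNA", "control")


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties going away from zero, as printed tables convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def skew(x_count: float, y_count: float) -> Optional[float]:
    """(x - y) / (x + y); ``None`` when the denominator is zero.

    Accepts raw counts or percentages; both give the same value for the
    same sequence since the total cancels.
    """
    if x_count < 0 or y_count < 0:
        raise MitocharError("skew inputs must be nonnegative")
    total = x_count + y_count
    if total == 0:
        return None
    return (x_count - y_count) / total


@dataclass(frozen=True)
class CompositionStats:
    """Base counts and derived composition statistics for one partition."""

    n_A: int
    n_C: int
    n_G: int
    n_T: int
    n_other: int = 0  # N characters: counted in length, not in percentages
    partition: str = "whole"

    @property
    def length(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T + self.n_other

    @property
    def n_counted(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_counted

    @property
    def pct_A(self) -> float:
        return self._pct(self.n_A)

    @property
    def pct_C(self) -> float:
        return self._pct(self.n_C)

    @property
    def pct_G(self) -> float:
        return self._pct(self.n_G)

    @property
    def pct_T(self) -> float:
        return self._pct(self.n_T)

    @property
    def at_content(self) -> float:
        return self.pct_A + self.pct_T

    @property
    def at_skew(self) -> Optional[float]:
        return skew(self.n_A, self.n_T)

    @property
    def gc_skew(self) -> Optional[float]:
        return skew(self.n_G, self.n_C)

    def as_row(self) -> dict:
        """Presentation row (printed-table column order and rounding)."""
        fmt3 = lambda v: None if v is None else round_half_up(v, 3)
        return {
            "partition": self.partition,
            "size_bp": self.length,
            "pct_A": round_half_up(self.pct_A, 2),
            "pct_G": round_half_up(self.pct_G, 2),
            "pct_T": round_half_up(self.pct_T, 2),
            "pct_C": round_half_up(self.pct_C, 2),
            "at_pct": round_half_up(self.at_content, 2),
            "at_skew": fmt3(self.at_skew),
            "gc_skew": fmt3(self.gc_skew),
        }


def base_composition(seq: str, partition: str = "whole") -> CompositionStats:
    """Exact base counts and composition statistics for a sequence."""
    if not seq:
        raise MitocharError("cannot compute composition of an empty sequence")
    s = seq.upper()
    n_a, n_c, n_g, n_t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    other = len(s) - (n_a + n_c + n_g + n_t)
    return CompositionStats(
        n_A=n_a, n_C=n_c, n_G=n_g, n_T=n_t, n_other=other, partition=partition
    )


_CLASS_BY_PARTITION = {
    "PCG": FeatureClass.PCG,
    "tRNA": FeatureClass.TRNA,
    "rRNA": FeatureClass.RRNA,
    "control": FeatureClass.CONTROL,
}


def partition_composition(
    genome: Mitogenome,
    table: AnnotationTable,
    partition_strand: str = "sense",
) -> dict[str, CompositionStats]:
    """Composition per annotation class plus the whole genome.

    Class statistics are computed on the concatenation, in table order, of
    each feature's gene-strand (sense) sequence; ``partition_strand="major"``
    uses the major-strand slice for every feature instead. The whole-genome
    row is always the major strand. Overlapping features contribute their
    full spans (double counting within a class is allowed, matching how
    printed partition sizes are derived from per-gene sizes). Classes with
    no features are omitted.
    """
    if partition_strand not in ("sense", "major"):
        raise ValueError("partition_strand must be 'sense' or 'major'")
    out: dict[str, CompositionStats] = {
        "whole": base_composition(genome.seq, partition="whole")
    }
    for part, cls in _CLASS_BY_PARTITION.items():
        feats = table.by_class(cls)
        if not feats:
            continue
        pieces = []
        for f in feats:
            if partition_strand == "sense":
                pieces.append(extract_gene_sequence(genome, f))
            else:
                from dataclasses import replace

                pieces.append(
                    extract_gene_sequence(genome, replace(f, strand=Strand.MAJOR))
                )
        out[part] = base_composition("".join(pieces), partition=part)
    return out


def coverage_fraction(part_len: int, genome_len: int) -> float:
    """Percentage of the genome occupied by a partition, rounded to 2 dp."""
    if genome_len <= 0:
        raise MitocharError("genome length must be positive")
    if part_len < 0:
        raise MitocharError("partition length must be nonnegative")
    return round_half_up(100.0 * part_len / genome_len, 2)
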