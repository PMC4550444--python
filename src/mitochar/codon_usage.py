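"""Codon-level analysis of mitochondrial protein-coding genes.

Everything here runs under the invertebrate mitochondrial genetic code
(translation table 5): 62 sense codons — AGA/AGG code for Ser, ATA for Met,
TGA for Trp — and two stops, TAA and TAG. Synonymous families use the
conventional mitochondrial split of the six-fold families: Leu1 = CTN,
Leu2 = TTA/TTG (UUR), Ser1 = AGN, Ser2 = TCN.

Mitochondrial CDSs may end in an incomplete stop (a terminal T or TA that
polyadenylation completes to TAA); :func:`classify_stop` recognizes these,
and :func:`codon_census` excludes stop codons and incomplete remnants from
sense-codon counts.

RSCU (relative synonymous codon usage) follows the standard Sharp-Li
definition: a codon's count divided by the mean count of its synonymous
family, so RSCU 1 means no bias within the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

from mitochar.errors import CodonUsageError

__all__ = [
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "StartCall",
    "StopCall",
    "StartStopReport",
    "CodonUsageTable",
    "classify_start",
    "classify_stop",
    "classify_gene",
    "codon_census",
    "rscu",
    "rank_amino_acids",
]

_AA_LONG = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "E": "Glu", "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile",
    "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro", "T": "Thr",
    "W": "Trp", "Y": "Tyr", "V": "Val", "S": "Ser", "L": "Leu",
}


class GeneticCode:
    """A codon table with mitochondrial family labels.

    Built from NCBI translation table 5 by default. ``family_of`` maps each
    sense codon to its synonymous-family label (three-letter amino acid
    name, with Leu and Ser split into Leu1/Leu2 and Ser1/Ser2).
    """

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.forward: dict[str, str] = dict(table.forward_table)
        self.stop_codons: frozenset[str] = frozenset(table.stop_codons)
        self.sense_codons: tuple[str, ...] = tuple(
            sorted(c for c in self.forward if set(c) <= set("ACGT"))
        )
        self.family_of: dict[str, str] = {
            codon: self._label(codon, aa) for codon, aa in self.forward.items()
        }
        self.families: dict[str, tuple[str, ...]] = {}
        for codon in self.sense_codons:
            self.families.setdefault(self.family_of[codon], [])  # type: ignore[arg-type]
        fam: dict[str, list[str]] = {label: [] for label in self.families}
        for codon in self.sense_codons:
            fam[self.family_of[codon]].append(codon)
        self.families = {label: tuple(v) for label, v in fam.items()}

    @staticmethod
    def _label(codon: str, aa: str) -> str:
        if aa == "L":
            return "Leu1" if codon.startswith("CT") else "Leu2"
        if aa == "S":
            return "Ser1" if codon.startswith("AG") else "Ser2"
        return _AA_LONG[aa]

    def translate(self, codon: str) -> str:
        """One-letter amino acid of a sense codon ('*' for a stop)."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            return "*"
        try:
            return self.forward[codon]
        except KeyError as exc:
            raise CodonUsageError(f"not a codon: {codon!r}") from exc


#: Shared default instance of the invertebrate mitochondrial code.
INVERTEBRATE_MITO = GeneticCode(5)


@dataclass(frozen=True)
class StartCall:
    codon: str
    canonical: bool  # ATN pattern


@dataclass(frozen=True)
class StopCall:
    token: str  # TAA / TAG / TA / T, or the trailing bases when unresolved
    status: str  # complete | incomplete | unresolved


@dataclass(frozen=True)
class StartStopReport:
    gene: str
    start: StartCall
    stop: StopCall


def classify_start(cds: str) -> StartCall:
    """First codon of a CDS; canonical iff it matches AT[ACGT]."""
    cds = cds.upper()
    if len(cds) < 6:
        raise CodonUsageError(f"CDS too short to classify ({len(cds)} nt)")
    codon = cds[:3]
    return StartCall(codon=codon, canonical=codon.startswith("AT"))


def classify_stop(cds: str) -> StopCall:
    """Terminal stop classification, recognizing incomplete T / TA stops.

    A CDS whose length is a multiple of 3 and ends in TAA/TAG has a complete
    stop; length = 1 (mod 3) ending in T, or 2 (mod 3) ending in TA, is an
    incomplete stop completed by polyadenylation. Anything else is reported
    as unresolved with the trailing bases as diagnostics.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise CodonUsageError(f"CDS too short to classify ({len(cds)} nt)")
    rem = len(cds) % 3
    if rem == 0 and cds[-3:] in ("TAA", "TAG"):
        return StopCall(token=cds[-3:], status="complete")
    if rem == 1 and cds[-1] == "T":
        return StopCall(token="T", status="incomplete")
    if rem == 2 and cds[-2:] == "TA":
        return StopCall(token="TA", status="incomplete")
    tail = cds[-3:] if rem == 0 else cds[-rem:]
    return StopCall(token=tail, status="unresolved")


def classify_gene(name: str, cds: str) -> StartStopReport:
    return StartStopReport(gene=name, start=classify_start(cds), stop=classify_stop(cds))


@dataclass
class CodonUsageTable:
    """Census of sense codons over a set of CDSs.

    ``counts`` covers all 62 sense codons (zeros included); ``stop_counts``
    tallies complete stop codons separately; incomplete stop remnants are
    dropped before counting.
    """

    counts: dict[str, int]
    stop_counts: dict[str, int]
    code: GeneticCode = field(default_factory=lambda: INVERTEBRATE_MITO, repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def per_thousand(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: 1000.0 * n / total for c, n in self.counts.items()}

    @property
    def missing(self) -> frozenset[str]:
        return frozenset(c for c, n in self.counts.items() if n == 0)

    @property
    def aa_totals(self) -> dict[str, int]:
        out: dict[str, int] = {label: 0 for label in self.code.families}
        for codon, n in self.counts.items():
            out[self.code.family_of[codon]] += n
        return out

    @property
    def rscu(self) -> dict[str, Optional[float]]:
        return rscu(self, self.code)


def codon_census(
    cds_list: Sequence[str],
    code: GeneticCode = INVERTEBRATE_MITO,
    names: Optional[Sequence[str]] = None,
    include_start: bool = True,
) -> CodonUsageTable:
    """Count sense codons across in-frame CDSs.

    Each CDS is read from frame 0; a terminal complete stop goes to
    ``stop_counts`` and a 1-2 nt incomplete remnant is discarded. An
    internal in-frame stop raises, naming the gene and codon position.
    ``include_start=False`` drops each CDS's first codon from the census
    (start codons are sense codons and are counted by default).
    """
    counts = {c: 0 for c in code.sense_codons}
    stop_counts = {c: 0 for c in sorted(code.stop_codons)}
    for idx, cds in enumerate(cds_list):
        gene = names[idx] if names else f"cds{idx + 1}"
        s = cds.upper()
        n_codons = len(s) // 3
        stop = classify_stop(s)
        body_end = n_codons
        if stop.status == "complete":
            stop_counts[stop.token] += 1
            body_end -= 1
        for k in range(body_end):
            codon = s[3 * k : 3 * k + 3]
            if codon in code.stop_codons:
                raise CodonUsageError(
                    f"{gene}: internal stop codon {codon} at codon position {k + 1}"
                )
            if codon not in counts:
                raise CodonUsageError(f"{gene}: unreadable codon {codon!r} at position {k + 1}")
            if k == 0 and not include_start:
                continue
            counts[codon] += 1
    return CodonUsageTable(counts=counts, stop_counts=stop_counts, code=code)


def rscu(
    table: CodonUsageTable, code: GeneticCode = INVERTEBRATE_MITO
) -> dict[str, Optional[float]]:
    """RSCU per codon: count divided by the family mean count.

    Families with zero total usage get ``None`` for every member (0/0).
    """
    out: dict[str, Optional[float]] = {}
    for label, codons in code.families.items():
        fam_total = sum(table.counts[c] for c in codons)
        if fam_total == 0:
            for c in codons:
                out[c] = None
            continue
        for c in codons:
            out[c] = table.counts[c] * len(codons) / fam_total
    return out


@dataclass(frozen=True)
class RankEntry:
    label: str
    count: int
    tied: bool


def rank_amino_acids(table: CodonUsageTable) -> list[RankEntry]:
    """Amino-acid families by descending usage; ties alphabetical, flagged."""
    totals = table.aa_totals
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    by_count: dict[int, int] = {}
    for _, n in ordered:
        by_count[n] = by_count.get(n, 0) + 1
    return [RankEntry(label=k, count=n, tied=by_count[n] > 1) for k, n in ordered]
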