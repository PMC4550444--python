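"""Feature scanners for A+T-rich control regions and intergenic spacers.

The scanners find the features an insect mitogenome's control region is
typically described by: short conserved motifs (e.g. ATAGA preceding the
replication-origin poly-T run, or the ATACTAA spacer motif), maximal
homopolymer tracts, perfect microsatellites (unit 1-6 nt) and approximate
tandem repeats (period >= 10, ungapped identity). All coordinates are
1-based within the scanned region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from mitochar.errors import MitocharError
from mitochar.mito_io import reverse_complement

__all__ = [
    "MotifHit",
    "PolyTract",
    "MicrosatelliteHit",
    "TandemRepeatHit",
    "ControlRegionReport",
    "find_motifs",
    "find_poly_tracts",
    "find_microsatellites",
    "find_tandem_repeats",
    "control_region_report",
]


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based within the scanned region
    strand: str = "given"  # or "reverse-complement"


@dataclass(frozen=True)
class PolyTract:
    base: str
    start: int
    length: int


@dataclass(frozen=True)
class MicrosatelliteHit:
    unit: str  # canonical rotation (lexicographically smallest phase present)
    copies: int
    start: int
    span: int  # = copies * len(unit); region[start..start+span-1] == unit*copies


@dataclass(frozen=True)
class TandemRepeatHit:
    period: int
    copies: float
    start: int
    span: int
    identity: float


def find_motifs(region: str, motif: str, both_strands: bool = False) -> list[MotifHit]:
    """All exact occurrences of ``motif``, left to right, overlaps allowed."""
    motif = motif.upper()
    if len(motif) < 3:
        raise MitocharError("motif must be at least 3 nt")
    if set(motif) - set("ACGT"):
        raise MitocharError(f"motif must be over ACGT, got {motif!r}")
    s = region.upper()
    hits: list[MotifHit] = []
    targets = [(motif, "given")]
    if both_strands:
        rc = reverse_complement(motif)
        if rc != motif:
            targets.append((rc, "reverse-complement"))
    for pattern, strand in targets:
        pos = s.find(pattern)
        while pos != -1:
            hits.append(MotifHit(motif=motif, start=pos + 1, strand=strand))
            pos = s.find(pattern, pos + 1)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def find_poly_tracts(region: str, base: str, min_len: int = 10) -> list[PolyTract]:
    """Maximal single-base runs of ``base`` at least ``min_len`` long."""
    base = base.upper()
    if base not in "ACGT" or len(base) != 1:
        raise MitocharError("base must be one of A, C, G, T")
    s = region.upper()
    out: list[PolyTract] = []
    i, n = 0, len(s)
    while i < n:
        if s[i] == base:
            j = i
            while j < n and s[j] == base:
                j += 1
            if j - i >= min_len:
                out.append(PolyTract(base=base, start=i + 1, length=j - i))
            i = j
        else:
            i += 1
    return out


def _is_primitive(unit: str) -> bool:
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def find_microsatellites(
    region: str, max_unit: int = 6, min_copies: int = 5
) -> list[MicrosatelliteHit]:
    """Maximal perfect microsatellites with a primitive unit of 1-6 nt.

    Within a maximal run the reported phase is chosen so the unit is the
    lexicographically smallest rotation achievable without losing a copy
    (so an AT-repeat is reported as (AT)n, never (TA)n). Runs whose unit is
    itself periodic (e.g. unit ATAT) are left to the smaller period.
    """
    s = region.upper()
    n = len(s)
    out: list[MicrosatelliteHit] = []
    for u in range(1, max_unit + 1):
        i = 0
        while i + u < n:
            if s[i] != s[i + u]:
                i += 1
                continue
            # maximal interval of period-u self-match starting at or before i
            j = i
            while j + u < n and s[j] == s[j + u]:
                j += 1
            # run covers s[i : j + u]; total length:
            total = (j + u) - i
            max_copies = total // u
            if max_copies >= min_copies:
                # choose the phase with max copies and smallest unit
                best: Optional[tuple[int, str, int]] = None  # (copies, unit, start0)
                for shift in range(u):
                    copies = (total - shift) // u
                    if copies < min_copies:
                        continue
                    unit = s[i + shift : i + shift + u]
                    if not _is_primitive(unit):
                        continue
                    cand = (copies, unit, i + shift)
                    if best is None or (-cand[0], cand[1], cand[2]) < (
                        -best[0],
                        best[1],
                        best[2],
                    ):
                        best = cand
                if best is not None:
                    copies, unit, start0 = best
                    out.append(
                        MicrosatelliteHit(
                            unit=unit, copies=copies, start=start0 + 1, span=copies * u
                        )
                    )
            # s[j] != s[j+u], so the next period-u run can start at j+1
            i = j + 1
    out.sort(key=lambda h: (h.start, len(h.unit)))
    return out


def find_tandem_repeats(
    region: str,
    min_period: int = 10,
    min_copies: float = 2.0,
    min_identity: float = 0.9,
) -> list[TandemRepeatHit]:
    """Approximate tandem repeats by period autocorrelation.

    For each candidate period p the region is compared against itself
    shifted by p. A p-wide window where at least ``min_identity`` of
    positions match seeds a repeat; within each contiguous stretch of
    qualifying window starts the best-identity window is taken and then
    extended outward through exact matches only, so a planted perfect
    duplication is reported with identity 1.0. Overlapping reports are
    merged keeping the highest identity (ties: longest span, smallest
    period). Identity is ungapped; there is no indel model.
    """
    s = region.upper()
    n = len(s)
    if n < 2 * min_period:
        return []
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    raw_hits: list[TandemRepeatHit] = []
    for p in range(min_period, n // 2 + 1):
        eq = (arr[:-p] == arr[p:]).astype(np.int32)
        if eq.size < p:
            continue
        csum = np.concatenate([[0], np.cumsum(eq)])
        limit = eq.size - p

        def ident(k: int) -> float:
            return (csum[k + p] - csum[k]) / p

        i = 0
        while i <= limit:
            if ident(i) < min_identity:
                i += 1
                continue
            # contiguous stretch of qualifying starts; take its best window
            j = i
            while j + 1 <= limit and ident(j + 1) >= min_identity:
                j += 1
            best = max(range(i, j + 1), key=lambda k: (ident(k), -k))
            lo, m = best, p
            while lo > 0 and eq[lo - 1]:
                lo -= 1
                m += 1
            while lo + m < eq.size and eq[lo + m]:
                m += 1
            span = m + p
            copies = span / p
            if copies >= min_copies:
                identity = (csum[lo + m] - csum[lo]) / m
                raw_hits.append(
                    TandemRepeatHit(
                        period=p,
                        copies=copies,
                        start=lo + 1,
                        span=span,
                        identity=float(identity),
                    )
                )
            i = max(j + 1, lo + m)
    return _merge_tandem_hits(raw_hits)


def _merge_tandem_hits(hits: list[TandemRepeatHit]) -> list[TandemRepeatHit]:
    ranked = sorted(hits, key=lambda h: (-h.identity, -h.span, h.period, h.start))
    kept: list[TandemRepeatHit] = []
    for h in ranked:
        h_end = h.start + h.span - 1
        overlap = False
        for k in kept:
            k_end = k.start + k.span - 1
            inter = min(h_end, k_end) - max(h.start, k.start) + 1
            if inter > 0 and inter >= 0.5 * min(h.span, k.span):
                overlap = True
                break
        if not overlap:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.period))
    return kept


@dataclass(frozen=True)
class ControlRegionReport:
    orientation: str  # "given" or "reverse-complement"
    motif_hits: tuple[MotifHit, ...]
    poly_t: tuple[PolyTract, ...]
    poly_a: tuple[PolyTract, ...]
    microsatellites: tuple[MicrosatelliteHit, ...]
    tandem_repeats: tuple[TandemRepeatHit, ...]
    flank_genes: tuple[str, ...] = ()


def control_region_report(
    region: str,
    flank_gene_names: Sequence[str] = (),
    motif: str = "ATAGA",
    revcomp: bool = False,
    poly_min: int = 10,
    microsat_max_unit: int = 6,
    microsat_min_copies: int = 5,
    tr_min_period: int = 10,
    tr_min_copies: float = 2.0,
    tr_min_identity: float = 0.9,
) -> ControlRegionReport:
    """Run all scanners on a control region with conventional defaults.

    ``revcomp=True`` scans the reverse complement (published control-region
    figures are often drawn on the reverse strand); coordinates are then in
    the reverse-complemented region.
    """
    if not region:
        return ControlRegionReport(
            orientation="reverse-complement" if revcomp else "given",
            motif_hits=(),
            poly_t=(),
            poly_a=(),
            microsatellites=(),
            tandem_repeats=(),
            flank_genes=tuple(flank_gene_names),
        )
    s = reverse_complement(region) if revcomp else region
    return ControlRegionReport(
        orientation="reverse-complement" if revcomp else "given",
        motif_hits=tuple(find_motifs(s, motif)),
        poly_t=tuple(find_poly_tracts(s, "T", poly_min)),
        poly_a=tuple(find_poly_tracts(s, "A", poly_min)),
        microsatellites=tuple(
            find_microsatellites(s, microsat_max_unit, microsat_min_copies)
        ),
        tandem_repeats=tuple(
            find_tandem_repeats(s, tr_min_period, tr_min_copies, tr_min_identity)
        ),
        flank_genes=tuple(flank_gene_names),
    )
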