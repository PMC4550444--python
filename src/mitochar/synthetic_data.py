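"""Seeded generator of fully annotated circular mitogenomes.

The generator emulates the structural and statistical properties a typical
lepidopteran mitogenome analysis assumes, so every downstream module can
be tested against planted ground truth: a ~15.4 kb circular, strongly
A+T-rich genome carrying 13 protein-coding genes, 22 tRNAs, 2 rRNAs and
one A+T-rich control region; the derived trnM-trnI-trnQ rearrangement at
the start of the gene order; a planted 7 bp atp8/atp6 overlap; a
noncanonical CGA start for cox1 and incomplete stop codons (T for
cox1/cox2, TA for nad4); tRNAs built arm-by-arm so they fold by
construction, with a planted G-U wobble in ten of them and a U-U acceptor
mismatch in trnA; and a control region containing an ATAGA motif followed
by an 18 bp poly-T run, an (AT)8 microsatellite and a poly-A element at
the trnM-proximal end.

Protein-coding sequence is drawn codon-by-codon from a stationary
AT-biased distribution (weight proportional to (A+T fraction)^gamma), so
AT-rich codons (AAT Asn, ATT Ile, AAA Lys, TAT Tyr, TTT Phe, TTA Leu2)
dominate naturally. Every planted feature is recorded in a GroundTruth
object; identical parameters and seed reproduce the output byte-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from mitochar.codon_usage import INVERTEBRATE_MITO, GeneticCode, classify_stop
from mitochar.errors import MitocharError
from mitochar.mito_io import (
    AnnotationTable,
    FeatureClass,
    GeneFeature,
    Mitogenome,
    Strand,
    reverse_complement,
)

__all__ = [
    "SimParams",
    "GenePlanEntry",
    "GroundTruth",
    "generate_mitogenome",
    "generate_taxon_family",
    "solve_trna_boundaries",
]


@dataclass(frozen=True)
class GenePlanEntry:
    """One gene in the genome template, with the gap to the next feature."""

    name: str
    cls: FeatureClass
    strand: Strand
    length: int
    gap_after: int  # negative = overlap with the next feature
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_token: Optional[str] = None  # TAA / TAG / TA / T


def _t(name, length, anticodon, gap):  # tRNA row helper
    return GenePlanEntry(name, FeatureClass.TRNA, Strand.MAJOR, length, gap, anticodon)


def _tm(name, length, anticodon, gap):  # minor-strand tRNA
    return GenePlanEntry(name, FeatureClass.TRNA, Strand.MINOR, length, gap, anticodon)


def _p(name, length, start, stop, gap, minor=False):
    return GenePlanEntry(
        name,
        FeatureClass.PCG,
        Strand.MINOR if minor else Strand.MAJOR,
        length,
        gap,
        start_codon=start,
        stop_token=stop,
    )


# Default template: published-like gene order (derived trnM-trnI-trnQ block
# first), published-like lengths, one planted overlap (atp8/atp6, 7 bp).
# PCG lengths are adjusted where a published length is inconsistent with a
# complete TAA stop (nad5 1743, nad1 939); other junction overlaps are
# relaxed to 1 bp spacers so tRNA ends stay intact for folding.
DEFAULT_GENE_PLAN: tuple[GenePlanEntry, ...] = (
    _t("trnM", 68, "CAT", 1),
    _t("trnI", 66, "GAT", 1),
    _tm("trnQ", 69, "TTG", 57),
    _p("nad2", 1014, "ATT", "TAA", 17),
    _t("trnW", 73, "TCA", 1),
    _tm("trnC", 69, "GCA", 2),
    _tm("trnY", 66, "GTA", 5),
    _p("cox1", 1531, "CGA", "T", 0),
    _t("trnL2", 67, "TAA", 0),
    _p("cox2", 682, "ATG", "T", 1),
    _t("trnK", 71, "CTT", 1),
    _t("trnD", 66, "GTC", 0),
    _p("atp8", 159, "ATC", "TAA", -7),
    _p("atp6", 678, "ATG", "TAA", 1),
    _p("cox3", 789, "ATG", "TAA", 2),
    _t("trnG", 66, "TCC", 0),
    _p("nad3", 354, "ATC", "TAA", 53),
    _t("trnA", 70, "TGC", 1),
    _t("trnR", 64, "TCG", 3),
    _t("trnN", 65, "GTT", 1),
    _t("trnS1", 70, "GCT", 1),
    _t("trnE", 68, "TTC", 1),
    _tm("trnF", 67, "GAA", 1),
    _p("nad5", 1743, "ATT", "TAA", 1, minor=True),
    _tm("trnH", 66, "GTG", 1),
    _p("nad4", 1343, "ATA", "TA", 1, minor=True),
    _p("nad4L", 288, "ATT", "TAA", 14, minor=True),
    _t("trnT", 65, "TGT", 0),
    _tm("trnP", 65, "TGG", 8),
    _p("nad6", 531, "ATT", "TAA", 14),
    _p("cob", 1149, "ATG", "TAA", 4),
    _t("trnS2", 67, "TGA", 18),
    _p("nad1", 939, "ATT", "TAA", 7, minor=True),
    _tm("trnL1", 71, "TAG", 0),
    GenePlanEntry("rrnL", FeatureClass.RRNA, Strand.MINOR, 1358, 0),
    _tm("trnV", 67, "TAC", 0),
    GenePlanEntry("rrnS", FeatureClass.RRNA, Strand.MINOR, 779, 0),
    GenePlanEntry("control_region", FeatureClass.CONTROL, Strand.MAJOR, 372, 0),
)

# Ten tRNAs carry one planted G-U wobble each (stem, pair index); trnA
# additionally carries a U-U acceptor-stem mismatch. All planted pairs sit
# in the acceptor, D or anticodon stems.
DEFAULT_WOBBLE_PLAN: dict[str, tuple[str, int]] = {
    "trnA": ("acceptor", 2),
    "trnC": ("D", 1),
    "trnQ": ("anticodon", 2),
    "trnG": ("acceptor", 3),
    "trnL1": ("acceptor", 1),
    "trnL2": ("D", 0),
    "trnF": ("anticodon", 1),
    "trnP": ("acceptor", 5),
    "trnS1": ("acceptor", 4),
    "trnV": ("D", 2),
}
DEFAULT_MISMATCH_PLAN: dict[str, tuple[str, int, str, str]] = {
    "trnA": ("acceptor", 4, "T", "T"),
}


@dataclass(frozen=True)
class ControlRegionPlan:
    length: int = 372
    motif: str = "ATAGA"
    poly_t_len: int = 18
    at_repeat_copies: int = 8
    poly_a_len: int = 12
    #: extra exact duplications to plant: list of periods (each occurs twice)
    duplications: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimParams:
    seed: int = 1
    at_content: float = 0.80
    gamma: float = 3.0  # AT bias exponent for codon draws
    gene_plan: tuple[GenePlanEntry, ...] = DEFAULT_GENE_PLAN
    control_region: ControlRegionPlan = ControlRegionPlan()
    wobble_plan: tuple[tuple[str, str, int], ...] = tuple(
        (k, v[0], v[1]) for k, v in sorted(DEFAULT_WOBBLE_PLAN.items())
    )
    mismatch_plan: tuple[tuple[str, str, int, str, str], ...] = tuple(
        (k, *v) for k, v in sorted(DEFAULT_MISMATCH_PLAN.items())
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.at_content < 1.0):
            raise MitocharError("at_content must be in (0, 1)")
        for e in self.gene_plan:
            if e.length <= 0:
                raise MitocharError(f"{e.name}: nonpositive length")
        for prev, nxt in zip(self.gene_plan, self.gene_plan[1:]):
            if prev.gap_after < 0 and -prev.gap_after >= min(prev.length, nxt.length):
                raise MitocharError(
                    f"planted overlap at {prev.name}/{nxt.name} is longer than a gene"
                )


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    codon_tally: dict[str, dict[str, int]]
    start_codons: dict[str, str]
    stop_tokens: dict[str, str]
    gaps: dict[tuple[str, str], int]
    cr_features: dict[str, tuple[int, int]]  # name -> (1-based start, length)
    trna_boundaries: dict[str, tuple[int, ...]]
    trna_wobble: dict[str, tuple[int, int]]  # 1-based (5', 3') positions in the tRNA
    trna_mismatch: dict[str, tuple[int, int, str, str]]
    tree_newick: Optional[str] = None

    def total_codon_tally(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tally in self.codon_tally.values():
            for codon, n in tally.items():
                out[codon] = out.get(codon, 0) + n
        return out


# ---------------------------------------------------------------------------
# base and codon draws

_BASES = np.array(list("ACGT"))


def _base_probs(at: float) -> np.ndarray:
    # slight A-over-T and C-over-G asymmetry, as in typical insect mtDNA
    return np.array([at * 0.515, (1 - at) * 0.62, (1 - at) * 0.38, at * 0.485])


def _draw_bases(rng: np.random.Generator, n: int, at: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(at))
    return "".join(_BASES[idx])


def _codon_weights(code: GeneticCode, gamma: float) -> tuple[list[str], np.ndarray]:
    codons = list(code.sense_codons)
    w = np.array(
        [((c.count("A") + c.count("T")) / 3.0) ** gamma for c in codons]
    )
    w = w / w.sum()
    return codons, w


def _draw_codons(
    rng: np.random.Generator, n: int, codons: list[str], w: np.ndarray
) -> list[str]:
    idx = rng.choice(len(codons), size=n, p=w)
    return [codons[i] for i in idx]


def _gen_cds(
    rng: np.random.Generator,
    length: int,
    start_codon: str,
    stop_token: str,
    codons: list[str],
    w: np.ndarray,
) -> str:
    stop_len = len(stop_token)
    body = length - 3 - stop_len
    if body < 0 or body % 3:
        raise MitocharError(
            f"CDS length {length} incompatible with start + {stop_token!r} stop"
        )
    return start_codon + "".join(_draw_codons(rng, body // 3, codons, w)) + stop_token


def _tally(cds: str) -> dict[str, int]:
    # sense codons only: drop a complete stop / incomplete remnant
    usable = len(cds) - (3 if len(cds) % 3 == 0 else len(cds) % 3)
    out: dict[str, int] = {}
    for k in range(0, usable, 3):
        c = cds[k : k + 3]
        out[c] = out.get(c, 0) + 1
    return out


# ---------------------------------------------------------------------------
# tRNA construction

#: boundary vector layout: (asl, g1, dsl, dloop, g2, vr, tsl, tloop, trail)


def solve_trna_boundaries(length: int, d_arm_is_loop: bool = False) -> tuple[int, ...]:
    """Deterministic arm boundaries for a tRNA of the given length.

    Stems are planted at their maximal lengths (acceptor 7, D 4,
    anticodon 5, T 5) so that no alternative geometry can out-pair the
    planted one; the slack goes to the variable region first, then the D
    loop. All values stay inside the folder's default bounds.
    """
    asl, g1, g2, tsl, tloop, trail = 7, 2, 1, 5, 7, 1
    if not d_arm_is_loop:
        dsl = 4
        base = asl + g1 + (2 * dsl + 3) + g2 + 17 + (2 * tsl + tloop) + asl + trail
        # base with minimal 3 nt D loop:
        extra = length - base
        if extra < 0:
            raise MitocharError(f"tRNA length {length} too short for the template")
        vr = min(extra, 5)
        dloop = 3 + (extra - vr)
        if dloop > 12:
            vr += dloop - 12
            dloop = 12
        if vr > 9:
            raise MitocharError(f"tRNA length {length} too long for the template")
        return (asl, g1, dsl, dloop, g2, vr, tsl, tloop, trail)
    # Loop-only D arm: with no D stem the split of the unpaired stretch
    # between spacer1, loop and spacer2 is score-degenerate, so plant the
    # lexicographically smallest split (the folder's deterministic
    # tie-break): minimal g1, then minimal loop given spacer bounds.
    dsl = 0
    fixed = asl + 17 + (2 * tsl + tloop) + asl + trail
    budget = length - fixed  # g1 + dloop + g2 + vr
    vr = max(0, budget - (1 + 14 + 2))
    if vr > 9:
        raise MitocharError(f"tRNA length {length} too long for the template")
    rem = budget - vr  # g1 + dloop + g2
    g1 = max(1, rem - 14 - 2)
    g2 = min(2, rem - g1 - 4)
    dloop = rem - g1 - g2
    if not (1 <= g1 <= 3 and 0 <= g2 <= 2 and 4 <= dloop <= 14):
        raise MitocharError(f"tRNA length {length} does not fit a loop-only D arm")
    return (asl, g1, dsl, dloop, g2, vr, tsl, tloop, trail)


_STEM_OFFSETS = {"acceptor": 0, "D": 1, "anticodon": 2, "T": 3}


def _gen_trna(
    rng: np.random.Generator,
    length: int,
    anticodon: str,
    at: float,
    d_arm_is_loop: bool,
    wobble: Optional[tuple[str, int]],
    mismatch: Optional[tuple[str, int, str, str]],
) -> tuple[str, tuple[int, ...], Optional[tuple[int, int]], Optional[tuple[int, int, str, str]]]:
    from mitochar.trna_fold import fold_cloverleaf

    v = solve_trna_boundaries(length, d_arm_is_loop)
    for _ in range(100):
        seq, wob, mis = _draw_trna_once(rng, length, anticodon, at, v, wobble, mismatch)
        # foldable by construction: the planted decomposition must be the
        # unique optimum; chance complementarity elsewhere forces a redraw
        if fold_cloverleaf(seq).boundaries == v:
            return seq, v, wob, mis
    raise MitocharError("could not build an unambiguously foldable tRNA")


def _draw_trna_once(
    rng: np.random.Generator,
    length: int,
    anticodon: str,
    at: float,
    v: tuple[int, ...],
    wobble: Optional[tuple[str, int]],
    mismatch: Optional[tuple[str, int, str, str]],
) -> tuple[str, Optional[tuple[int, int]], Optional[tuple[int, int, str, str]]]:
    asl, g1, dsl, dloop, g2, vr, tsl, tloop, trail = v
    seq = [""] * length

    def fill(start: int, n: int) -> None:
        chunk = _draw_bases(rng, n, at)
        for k in range(n):
            seq[start + k] = chunk[k]

    def fill_a(start: int, n: int) -> None:
        # spacer/discriminator positions are fixed to A so that shifted
        # geometries cannot recruit them into chance stem pairs
        for k in range(n):
            seq[start + k] = "A"

    def stem(i: int, j: int, n: int) -> list[tuple[int, int]]:
        pairs = []
        side = _draw_bases(rng, n, at)
        comp = reverse_complement(side)  # complement, reversed
        for p in range(n):
            seq[i + p] = side[p]
            seq[j - p] = comp[n - 1 - p]
            pairs.append((i + p, j - p))
        return pairs

    d0 = asl + g1
    d_region = 2 * dsl + dloop
    ac0 = d0 + d_region + g2
    t0 = ac0 + 17 + vr

    stems: dict[str, list[tuple[int, int]]] = {}
    stems["acceptor"] = stem(0, length - trail - 1, asl)
    fill_a(asl, g1)
    if dsl:
        stems["D"] = stem(d0, d0 + d_region - 1, dsl)
        fill(d0 + dsl, dloop)
    else:
        # loop-only D arm: a poly-A tract cannot base-pair with itself, so
        # no alternative geometry can fold a stem out of this region
        stems["D"] = []
        for k in range(dloop):
            seq[d0 + k] = "A"
    fill_a(d0 + d_region, g2)
    stems["anticodon"] = stem(ac0, ac0 + 16, 5)
    loop0 = ac0 + 5
    fill(loop0, 2)
    for k, b in enumerate(anticodon):
        seq[loop0 + 2 + k] = b
    fill(loop0 + 5, 2)
    if vr:
        fill(ac0 + 17, vr)
    stems["T"] = stem(t0, t0 + 2 * tsl + tloop - 1, tsl)
    fill(t0 + tsl, tloop)
    if trail:
        fill_a(length - trail, trail)

    planted_wobble = None
    if wobble is not None:
        stem_name, idx = wobble
        i, j = stems[stem_name][idx]
        seq[i], seq[j] = "G", "T"
        planted_wobble = (i + 1, j + 1)
    planted_mismatch = None
    if mismatch is not None:
        stem_name, idx, b5, b3 = mismatch
        i, j = stems[stem_name][idx]
        seq[i], seq[j] = b5, b3
        planted_mismatch = (i + 1, j + 1, b5, b3)
    return "".join(seq), planted_wobble, planted_mismatch


# ---------------------------------------------------------------------------
# control region


def _has_spurious_features(s: str, plan: ControlRegionPlan, planted: dict) -> bool:
    from mitochar.control_region import (
        find_microsatellites,
        find_motifs,
        find_poly_tracts,
    )

    # Planted features must be unambiguously recoverable: the motif occurs
    # exactly once, the planted poly-tracts are the unique runs >= 10 of
    # their base, and the (AT)n repeat is the unique 2-nt microsatellite
    # with that many copies. Shorter homopolymer runs in the filler are
    # natural A+T-rich texture and are left alone.
    if {h.start for h in find_motifs(s, plan.motif)} != {planted[plan.motif][0]}:
        return True
    if {(t.start, t.length) for t in find_poly_tracts(s, "T", 10)} != {
        planted["poly_T"]
    }:
        return True
    if {(t.start, t.length) for t in find_poly_tracts(s, "A", 10)} != {
        planted["poly_A"]
    }:
        return True
    at_hits = {
        (h.start, h.copies)
        for h in find_microsatellites(s, 6, 5)
        if len(h.unit) == 2 and h.copies >= plan.at_repeat_copies
    }
    if at_hits != {(planted["AT_repeat"][0], plan.at_repeat_copies)}:
        return True
    return False


def _gen_control_region(
    rng: np.random.Generator, plan: ControlRegionPlan, at: float = 0.94
) -> tuple[str, dict[str, tuple[int, int]]]:
    dup_span = sum(2 * p for p in plan.duplications)
    fixed = (
        len(plan.motif)
        + plan.poly_t_len
        + 2 * plan.at_repeat_copies
        + plan.poly_a_len
        + 4  # guard bases
        + dup_span
        + len(plan.duplications)  # one guard base before each duplication
    )
    filler_total = plan.length - fixed - 40 - 60
    if filler_total < 0:
        raise MitocharError("control-region plan does not fit in its length")
    for _ in range(500):
        f1 = _draw_bases(rng, 40, at)
        f2 = _draw_bases(rng, 60, at)
        f3 = _draw_bases(rng, filler_total, at)
        dup_blocks = []
        for period in plan.duplications:
            unit = _draw_bases(rng, period, at)
            dup_blocks.append(unit + unit)
        parts: list[str] = []
        planted: dict[str, tuple[int, int]] = {}
        pos = 0

        def add(piece: str, name: Optional[str] = None) -> None:
            nonlocal pos
            if name:
                planted[name] = (pos + 1, len(piece))
            parts.append(piece)
            pos += len(piece)

        add(f1)
        add(plan.motif, plan.motif)
        add("T" * plan.poly_t_len, "poly_T")
        add("C")
        add(f2)
        add("C")
        add("AT" * plan.at_repeat_copies, "AT_repeat")
        add("C")
        add(f3)
        for k, block in enumerate(dup_blocks):
            add("G")
            add(block, f"duplication_{plan.duplications[k]}bp")
        add("C")
        add("A" * plan.poly_a_len, "poly_A")
        s = "".join(parts)
        assert len(s) == plan.length, (len(s), plan.length)
        if not _has_spurious_features(s, plan, planted):
            return s, planted
    raise MitocharError("could not draw a control region free of spurious features")


# ---------------------------------------------------------------------------
# genome assembly


def _gen_pcg_pair_with_overlap(
    rng: np.random.Generator,
    prev: GenePlanEntry,
    nxt: GenePlanEntry,
    overlap: int,
    codons: list[str],
    w: np.ndarray,
    code: GeneticCode,
) -> tuple[str, str]:
    """Draw two same-strand PCGs whose sequences share `overlap` bases.

    The downstream gene's reading frame takes precedence in the shared
    window: the upstream gene's tail is overwritten by the downstream
    gene's head, and the draw is retried until the upstream gene still
    ends with its planned stop and stays free of internal stops.
    """
    if prev.strand is not nxt.strand:
        raise MitocharError("planted overlaps require both genes on one strand")
    for _ in range(5000):
        seq_next = _gen_cds(rng, nxt.length, nxt.start_codon, nxt.stop_token, codons, w)
        seq_prev = _gen_cds(rng, prev.length, prev.start_codon, prev.stop_token, codons, w)
        merged = seq_prev[: prev.length - overlap] + seq_next[:overlap]
        stop = classify_stop(merged)
        expected_status = "complete" if len(prev.stop_token) == 3 else "incomplete"
        if stop.token != prev.stop_token or stop.status != expected_status:
            continue
        usable = prev.length - (3 if prev.length % 3 == 0 else prev.length % 3)
        if any(
            merged[k : k + 3] in code.stop_codons for k in range(0, usable, 3)
        ):
            continue
        return merged, seq_next
    raise MitocharError(
        f"could not satisfy the {overlap} bp overlap between {prev.name} and {nxt.name}"
    )


def generate_mitogenome(
    params: SimParams = SimParams(),
) -> tuple[Mitogenome, AnnotationTable, GroundTruth]:
    """Generate one annotated mitogenome with full ground truth.

    Deterministic under ``params.seed``: identical parameters reproduce the
    genome, annotation and ground truth byte-exactly.
    """
    rng = np.random.default_rng(params.seed)
    code = INVERTEBRATE_MITO
    codons, w = _codon_weights(code, params.gamma)
    at = params.at_content

    plan = params.gene_plan
    wobble_by = {name: (stem, idx) for name, stem, idx in params.wobble_plan}
    mism_by = {name: (stem, idx, b5, b3) for name, stem, idx, b5, b3 in params.mismatch_plan}

    # sense-strand sequences per gene
    seqs: dict[str, str] = {}
    gt = GroundTruth(
        codon_tally={},
        start_codons={},
        stop_tokens={},
        gaps={},
        cr_features={},
        trna_boundaries={},
        trna_wobble={},
        trna_mismatch={},
    )
    i = 0
    while i < len(plan):
        entry = plan[i]
        if entry.cls is FeatureClass.PCG and entry.gap_after < 0:
            nxt = plan[i + 1]
            if nxt.cls is not FeatureClass.PCG:
                raise MitocharError(
                    f"planted overlap after {entry.name} requires a PCG neighbour"
                )
            merged, seq_next = _gen_pcg_pair_with_overlap(
                rng, entry, nxt, -entry.gap_after, codons, w, code
            )
            seqs[entry.name] = merged
            seqs[nxt.name] = seq_next
            for e, s in ((entry, merged), (nxt, seq_next)):
                gt.codon_tally[e.name] = _tally(s)
                gt.start_codons[e.name] = e.start_codon
                gt.stop_tokens[e.name] = e.stop_token
            i += 2
            continue
        if entry.cls is FeatureClass.PCG:
            s = _gen_cds(rng, entry.length, entry.start_codon, entry.stop_token, codons, w)
            seqs[entry.name] = s
            gt.codon_tally[entry.name] = _tally(s)
            gt.start_codons[entry.name] = entry.start_codon
            gt.stop_tokens[entry.name] = entry.stop_token
        elif entry.cls is FeatureClass.TRNA:
            s, v, wob, mis = _gen_trna(
                rng,
                entry.length,
                entry.anticodon,
                at=min(0.86, at + 0.02),
                d_arm_is_loop=(entry.name == "trnS1"),
                wobble=wobble_by.get(entry.name),
                mismatch=mism_by.get(entry.name),
            )
            seqs[entry.name] = s
            gt.trna_boundaries[entry.name] = v
            if wob:
                gt.trna_wobble[entry.name] = wob
            if mis:
                gt.trna_mismatch[entry.name] = mis
        elif entry.cls is FeatureClass.RRNA:
            seqs[entry.name] = _draw_bases(rng, entry.length, min(0.9, at + 0.04))
        else:  # control region
            s, planted = _gen_control_region(rng, params.control_region)
            seqs[entry.name] = s
            gt.cr_features = planted
        i += 1

    # assemble the genome (major strand), left to right with planned gaps
    genome_parts: list[str] = []
    features: list[GeneFeature] = []
    cursor = 1  # 1-based start of the next feature
    genome_len = 0
    for k, entry in enumerate(plan):
        sense = seqs[entry.name]
        major = reverse_complement(sense) if entry.strand is Strand.MINOR else sense
        if cursor - 1 < genome_len:
            # overlap with the previous feature: the shared window must agree
            overlap = genome_len - (cursor - 1)
            tail = "".join(genome_parts)[-overlap:]
            if major[:overlap] != tail:
                raise MitocharError(f"overlap conflict while placing {entry.name}")
            genome_parts.append(major[overlap:])
            genome_len += len(major) - overlap
        else:
            genome_parts.append(major)
            genome_len += len(major)
        start = cursor
        end = start + entry.length - 1
        features.append(
            GeneFeature(
                name=entry.name,
                cls=entry.cls,
                strand=entry.strand,
                start=start,
                end=end,
                anticodon=entry.anticodon,
                declared_size=entry.length,
                start_codon=entry.start_codon,
                stop_codon=entry.stop_token,
            )
        )
        if k < len(plan) - 1:
            gt.gaps[(entry.name, plan[k + 1].name)] = entry.gap_after
            if entry.gap_after > 0:
                genome_parts.append(_draw_bases(rng, entry.gap_after, at))
                genome_len += entry.gap_after
            cursor = end + entry.gap_after + 1
    genome = Mitogenome(id=f"synthetic_mitogenome_seed{params.seed}", seq="".join(genome_parts))
    table = AnnotationTable(
        features=features, genome_length=genome.length, source="synthetic"
    )
    return genome, table, gt


# ---------------------------------------------------------------------------
# tree mode


def _jc_evolve(rng: np.random.Generator, arr: np.ndarray, d: float) -> np.ndarray:
    """One JC69 branch: each site substitutes with prob (3/4)(1-e^{-4d/3})."""
    if d < 0:
        raise MitocharError(f"negative branch length {d}")
    if d == 0:
        return arr.copy()
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    mask = rng.random(arr.size) < p
    out = arr.copy()
    out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


_B2I = {b: i for i, b in enumerate("ACGT")}
_I2B = np.array(list("ACGT"))


def generate_taxon_family(
    params: SimParams,
    tree_newick: str,
) -> tuple[list[tuple[str, Mitogenome, AnnotationTable]], str]:
    """Evolve a root genome along a tree under Jukes-Cantor substitution.

    ``tree_newick`` gives the true tree with branch lengths in expected
    substitutions per site; leaf labels name the taxa. Substitution is
    unconstrained on all sites (annotation coordinates are preserved; no
    indels). Returns the taxon genomes, each sharing the root annotation,
    and the true tree.
    """
    root_genome, table, _ = generate_mitogenome(params)
    tree = dendropy.Tree.get(
        data=tree_newick, schema="newick", preserve_underscores=True
    )
    rng = np.random.default_rng(params.seed + 101)
    root_arr = np.array([_B2I[b] for b in root_genome.seq], dtype=np.int8)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_arr}
    out: list[tuple[str, Mitogenome, AnnotationTable]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_arr = states[id(node.parent_node)]
        d = node.edge.length if node.edge.length is not None else 0.0
        arr = _jc_evolve(rng, parent_arr, float(d))
        states[id(node)] = arr
        if node.is_leaf():
            name = node.taxon.label if node.taxon else f"taxon{len(out) + 1}"
            seq = "".join(_I2B[arr])
            out.append((name, Mitogenome(id=name, seq=seq), table))
    return out, tree_newick
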