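"""Constrained cloverleaf folding of mitochondrial tRNA genes.

The fold is found by exhaustive enumeration over arm-boundary placements
(not by free-energy minimization): every admissible decomposition of the
sequence into acceptor stem, D arm, anticodon arm, variable region and T
arm is scored — Watson-Crick pairs +2, G-U wobble pairs +1, tolerated
in-stem mismatches -1 by default — and the maximum-score structure is
returned, with ties broken by the lexicographically smallest boundary
vector so refolding is bit-identical. The search space for a 60-80 nt
sequence is well under 10^5 candidates.

Input is kept as DNA; T is treated as U for pairing purposes, so a G-T
pair in the gene is reported as a G-U wobble in the folded RNA. A D region
that cannot form a stem may collapse to a bare loop (``d_arm_is_loop``),
the typical state of mitochondrial trnS1(AGN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from mitochar.codon_usage import INVERTEBRATE_MITO, GeneticCode
from mitochar.errors import MitocharError
from mitochar.mito_io import reverse_complement

__all__ = [
    "FoldParams",
    "CloverleafStructure",
    "MismatchCensus",
    "fold_cloverleaf",
    "locate_anticodon",
    "mismatch_census",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class FoldParams:
    """Scores and geometric bounds for the boundary-vector search."""

    wc_score: int = 2
    wobble_score: int = 1
    mismatch_score: int = -1
    acceptor_range: tuple[int, int] = (6, 7)
    spacer1_range: tuple[int, int] = (1, 3)
    d_stem_range: tuple[int, int] = (0, 4)
    d_loop_range: tuple[int, int] = (3, 12)
    d_region_loop_range: tuple[int, int] = (4, 14)  # when the D arm is a bare loop
    spacer2_range: tuple[int, int] = (0, 2)
    anticodon_stem: int = 5
    anticodon_loop: int = 7
    variable_range: tuple[int, int] = (0, 9)
    t_stem_range: tuple[int, int] = (2, 5)
    t_loop_range: tuple[int, int] = (3, 12)
    trail_range: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        if not (self.wc_score > self.wobble_score > 0 > self.mismatch_score):
            raise MitocharError("scores must satisfy WC > wobble > 0 > mismatch")


@dataclass(frozen=True)
class CloverleafStructure:
    """Arm/loop decomposition of one tRNA. Positions are 1-based.

    Stem pairs are (5'-position, 3'-position) tuples; every stem position
    is listed whether it forms a Watson-Crick pair, a G-U wobble (also in
    ``wobble_pairs``) or a tolerated mismatch (also in ``mismatches``,
    with the two bases and the stem name).
    """

    seq: str
    boundaries: tuple[int, ...]  # (asl, g1, dsl, dloop, g2, vr, tsl, tloop, trail)
    acceptor_pairs: tuple[tuple[int, int], ...]
    d_pairs: tuple[tuple[int, int], ...]
    d_loop_span: tuple[int, int]
    d_arm_is_loop: bool
    anticodon_pairs: tuple[tuple[int, int], ...]
    anticodon_loop_span: tuple[int, int]
    anticodon: str
    variable_span: Optional[tuple[int, int]]
    t_pairs: tuple[tuple[int, int], ...]
    t_loop_span: tuple[int, int]
    wobble_pairs: tuple[tuple[int, int, str], ...]
    mismatches: tuple[tuple[int, int, str, str, str], ...]
    score: int
    cloverleaf: bool

    @property
    def anticodon_loop_length(self) -> int:
        a, b = self.anticodon_loop_span
        return b - a + 1

    def stem_pairs(self) -> dict[str, tuple[tuple[int, int], ...]]:
        return {
            "acceptor": self.acceptor_pairs,
            "D": self.d_pairs,
            "anticodon": self.anticodon_pairs,
            "T": self.t_pairs,
        }

    def dot_bracket(self) -> str:
        """Dot-bracket string; only WC and wobble pairs get brackets."""
        chars = ["."] * len(self.seq)
        mis = {(i, j) for i, j, *_ in self.mismatches}
        for pairs in self.stem_pairs().values():
            for i, j in pairs:
                if (i, j) in mis:
                    continue
                chars[i - 1] = "("
                chars[j - 1] = ")"
        return "".join(chars)


def _pair_score(a: str, b: str, params: FoldParams) -> int:
    if (a, b) in _WC:
        return params.wc_score
    if (a, b) in _WOBBLE:
        return params.wobble_score
    return params.mismatch_score


def fold_cloverleaf(seq: str, params: Optional[FoldParams] = None) -> CloverleafStructure:
    """Best-scoring cloverleaf decomposition of a 60-80 nt sequence.

    Exhaustive over all boundary vectors satisfying the bounds in
    ``params``; deterministic (ties go to the lexicographically smallest
    vector). If even the best structure has fewer than six non-mismatch
    acceptor-stem pairs the result is flagged ``cloverleaf=False`` and
    returned best-effort.
    """
    params = params or FoldParams()
    s = seq.upper().replace("U", "T")
    L = len(s)
    if not (60 <= L <= 80):
        raise MitocharError(f"sequence length {L} outside the 60-80 nt cloverleaf range")
    if set(s) - set("ACGT"):
        raise MitocharError("sequence must be over ACGT/U")

    score_cache: dict[tuple[int, int, int], int] = {}

    def stem_score(i: int, j: int, n: int) -> int:
        # pairs (i+p, j-p) for p in range(n); 0-based indices
        key = (i, j, n)
        got = score_cache.get(key)
        if got is None:
            got = 0
            for p in range(n):
                got += _pair_score(s[i + p], s[j - p], params)
            score_cache[key] = got
        return got

    ac_arm = 2 * params.anticodon_stem + params.anticodon_loop  # 17 by default
    best_score: Optional[int] = None
    best_v: Optional[tuple[int, ...]] = None

    a_lo, a_hi = params.acceptor_range
    g1_lo, g1_hi = params.spacer1_range
    ds_lo, ds_hi = params.d_stem_range
    g2_lo, g2_hi = params.spacer2_range
    v_lo, v_hi = params.variable_range
    t_lo, t_hi = params.t_stem_range
    tl_lo, tl_hi = params.t_loop_range
    tr_lo, tr_hi = params.trail_range

    for asl in range(a_lo, a_hi + 1):
        for g1 in range(g1_lo, g1_hi + 1):
            for dsl in range(ds_lo, ds_hi + 1):
                if dsl == 0:
                    dl_lo, dl_hi = params.d_region_loop_range
                else:
                    dl_lo, dl_hi = params.d_loop_range
                for dloop in range(dl_lo, dl_hi + 1):
                    d_region = 2 * dsl + dloop
                    for g2 in range(g2_lo, g2_hi + 1):
                        head = asl + g1 + d_region + g2 + ac_arm
                        for vr in range(v_lo, v_hi + 1):
                            for tsl in range(t_lo, t_hi + 1):
                                for trail in range(tr_lo, tr_hi + 1):
                                    tloop = L - (head + vr + 2 * tsl + asl + trail)
                                    if not (tl_lo <= tloop <= tl_hi):
                                        continue
                                    d0 = asl + g1
                                    ac0 = d0 + d_region + g2
                                    t0 = ac0 + ac_arm + vr
                                    sc = stem_score(0, L - trail - 1, asl)
                                    sc += stem_score(ac0, ac0 + ac_arm - 1, params.anticodon_stem)
                                    sc += stem_score(t0, t0 + 2 * tsl + tloop - 1, tsl)
                                    if dsl:
                                        sc += stem_score(d0, d0 + d_region - 1, dsl)
                                    v = (asl, g1, dsl, dloop, g2, vr, tsl, tloop, trail)
                                    if (
                                        best_score is None
                                        or sc > best_score
                                        or (sc == best_score and v < best_v)  # type: ignore[operator]
                                    ):
                                        best_score, best_v = sc, v
    if best_v is None:
        raise MitocharError("no admissible cloverleaf geometry for this length")
    return _build_structure(s, best_v, best_score, params)  # type: ignore[arg-type]


def _build_structure(
    s: str, v: tuple[int, ...], score: int, params: FoldParams
) -> CloverleafStructure:
    L = len(s)
    asl, g1, dsl, dloop, g2, vr, tsl, tloop, trail = v
    ac_stem, ac_loop = params.anticodon_stem, params.anticodon_loop
    d0 = asl + g1
    d_region = 2 * dsl + dloop
    ac0 = d0 + d_region + g2
    t0 = ac0 + 2 * ac_stem + ac_loop + vr

    wobble: list[tuple[int, int, str]] = []
    mismatch: list[tuple[int, int, str, str, str]] = []

    def stem_pairs(i: int, j: int, n: int, name: str) -> tuple[tuple[int, int], ...]:
        out = []
        for p in range(n):
            a, b = i + p, j - p
            ba, bb = s[a], s[b]
            if (ba, bb) in _WOBBLE:
                wobble.append((a + 1, b + 1, name))
            elif (ba, bb) not in _WC:
                mismatch.append((a + 1, b + 1, ba, bb, name))
            out.append((a + 1, b + 1))
        return tuple(out)

    acc_pairs = stem_pairs(0, L - trail - 1, asl, "acceptor")
    d_pairs = stem_pairs(d0, d0 + d_region - 1, dsl, "D") if dsl else ()
    ac_pairs = stem_pairs(ac0, ac0 + 2 * ac_stem + ac_loop - 1, ac_stem, "anticodon")
    t_pairs = stem_pairs(t0, t0 + 2 * tsl + tloop - 1, tsl, "T")

    loop_start = ac0 + ac_stem  # 0-based
    anticodon = s[loop_start + 2 : loop_start + 5]
    mis_set = {(i, j) for i, j, *_ in mismatch}
    acc_good = sum(1 for p in acc_pairs if p not in mis_set)
    var_start = ac0 + 2 * ac_stem + ac_loop
    return CloverleafStructure(
        seq=s,
        boundaries=v,
        acceptor_pairs=acc_pairs,
        d_pairs=d_pairs,
        d_loop_span=(d0 + dsl + 1, d0 + dsl + dloop),
        d_arm_is_loop=(dsl == 0),
        anticodon_pairs=ac_pairs,
        anticodon_loop_span=(loop_start + 1, loop_start + ac_loop),
        anticodon=anticodon,
        variable_span=(var_start + 1, var_start + vr) if vr else None,
        t_pairs=t_pairs,
        t_loop_span=(t0 + tsl + 1, t0 + tsl + tloop),
        wobble_pairs=tuple(wobble),
        mismatches=tuple(mismatch),
        score=score,
        cloverleaf=acc_good >= 6,
    )


def locate_anticodon(
    structure: CloverleafStructure,
    seq: Optional[str] = None,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[str, str]:
    """Anticodon triplet (loop positions 3-5, 5'->3') and decoded amino acid.

    The decoded amino acid is the translation of the reverse complement of
    the anticodon under the invertebrate mitochondrial code, so e.g. TCA
    decodes Trp (TGA is a sense codon in this code).
    """
    if structure.anticodon_loop_length != 7:
        raise MitocharError(
            f"anticodon loop is {structure.anticodon_loop_length} nt, expected 7"
        )
    s = (seq or structure.seq).upper().replace("U", "T")
    a, _ = structure.anticodon_loop_span
    triplet = s[a + 1 : a + 4]  # loop positions 3-5, 1-based span starts at a
    codon = reverse_complement(triplet)
    return triplet, code.translate(codon)


@dataclass(frozen=True)
class MismatchCensus:
    """Pair-type totals over a folded tRNA set."""

    wobble_total: int
    wobble_by_trna: dict[str, tuple[tuple[int, int, str], ...]]
    mismatch_records: tuple[tuple[str, str, int, int, str, str], ...]
    # (trna, stem, pos5, pos3, base5, base3)

    @property
    def mismatch_total(self) -> int:
        return len(self.mismatch_records)


def mismatch_census(
    structures: Mapping[str, CloverleafStructure],
) -> MismatchCensus:
    """Wobble and mismatch totals across a set of folded tRNAs.

    Locations are classified by stem (acceptor / D / anticodon / T).
    """
    wobble_by: dict[str, tuple[tuple[int, int, str], ...]] = {}
    total = 0
    mism: list[tuple[str, str, int, int, str, str]] = []
    for name, st in structures.items():
        if st.wobble_pairs:
            wobble_by[name] = st.wobble_pairs
            total += len(st.wobble_pairs)
        for i, j, ba, bb, stem in st.mismatches:
            mism.append((name, stem, i, j, ba, bb))
    return MismatchCensus(
        wobble_total=total,
        wobble_by_trna=wobble_by,
        mismatch_records=tuple(mism),
    )
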