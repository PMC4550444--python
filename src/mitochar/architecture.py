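"""Junction ledger and gene-order comparison for circular annotations.

The gap between two consecutive features is ``next.start - prev.end - 1``:
negative values are overlaps of ``|gap|`` bp, zero means abutting features,
positive values are intergenic spacers. On a circular genome there is
exactly one wrap junction (last feature back to the first, through the
origin). Summaries conventionally exclude junctions that touch the control
region and the wrap junction, matching how published overlap/spacer
censuses are tallied.

Gene-order comparison uses circular, rotation-invariant adjacency sets;
the breakpoint count is the number of adjacencies present in one order but
not the other, which detects rearrangements such as the lepidopteran
trnM-trnI-trnQ block versus the ancestral insect trnI-trnQ-trnM.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

from mitochar.errors import MitocharError, ValidationError
from mitochar.mito_io import AnnotationTable, FeatureClass, GeneFeature, Strand

__all__ = [
    "JunctionRecord",
    "LedgerSummary",
    "OrderComparison",
    "junction_ledger",
    "summarize_ledger",
    "compare_order",
    "ancestral_insect_order",
]


@dataclass(frozen=True)
class JunctionRecord:
    prev_gene: str
    next_gene: str
    gap_bp: int
    wrap: bool = False
    involves_control: bool = False


@dataclass(frozen=True)
class LedgerSummary:
    n_overlaps: int
    total_overlap_bp: int
    max_overlap: int
    longest_overlap_pair: Optional[tuple[str, str]]
    n_spacers: int
    total_spacer_bp: int
    max_spacer: int
    min_spacer: int
    longest_spacer_pair: Optional[tuple[str, str]]


@dataclass(frozen=True)
class OrderComparison:
    observed: tuple[str, ...]
    reference: tuple[str, ...]
    breakpoints: int
    displaced: tuple[str, ...]


def junction_ledger(
    table: AnnotationTable,
    circular: bool = True,
    use_declared: bool = False,
) -> list[JunctionRecord]:
    """One record per adjacent feature pair, in genome order.

    With ``circular=True`` a final wrap record joins the last feature back
    to the first; its gap accounts for the origin (and is negative when the
    last feature wraps past the first feature's start). ``use_declared``
    substitutes each feature's verbatim declared intergenic value for the
    coordinate-derived gap where one is present, reproducing a printed
    table column even when it disagrees with its own coordinates.
    """
    feats = table.features
    if len(feats) < 2:
        return []
    keys = [(f.start, f.end) for f in feats]
    if keys != sorted(keys):
        raise ValidationError("junction_ledger requires features sorted in genome order")
    records: list[JunctionRecord] = []
    for prev, nxt in zip(feats, feats[1:]):
        gap = nxt.start - prev.end - 1
        if use_declared and prev.declared_intergenic is not None:
            gap = prev.declared_intergenic
        records.append(
            JunctionRecord(
                prev_gene=prev.name,
                next_gene=nxt.name,
                gap_bp=gap,
                involves_control=FeatureClass.CONTROL in (prev.cls, nxt.cls),
            )
        )
    if circular:
        last, first = feats[-1], feats[0]
        gap = first.start + table.genome_length - last.end - 1
        if use_declared and last.declared_intergenic is not None:
            gap = last.declared_intergenic
        records.append(
            JunctionRecord(
                prev_gene=last.name,
                next_gene=first.name,
                gap_bp=gap,
                wrap=True,
                involves_control=FeatureClass.CONTROL in (last.cls, first.cls),
            )
        )
    return records


def summarize_ledger(
    ledger: Sequence[JunctionRecord],
    include_control: bool = False,
    include_wrap: bool = False,
) -> LedgerSummary:
    """Overlap and spacer statistics over a junction ledger.

    By default junctions touching the control region and the wrap junction
    are excluded, matching the printed-census convention.
    """
    kept = [
        r
        for r in ledger
        if (include_control or not r.involves_control)
        and (include_wrap or not r.wrap)
    ]
    overlaps = [r for r in kept if r.gap_bp < 0]
    spacers = [r for r in kept if r.gap_bp > 0]
    max_over = max((-r.gap_bp for r in overlaps), default=0)
    over_pair = next(
        ((r.prev_gene, r.next_gene) for r in overlaps if -r.gap_bp == max_over), None
    )
    max_sp = max((r.gap_bp for r in spacers), default=0)
    sp_pair = next(
        ((r.prev_gene, r.next_gene) for r in spacers if r.gap_bp == max_sp), None
    )
    return LedgerSummary(
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(-r.gap_bp for r in overlaps),
        max_overlap=max_over,
        longest_overlap_pair=over_pair,
        n_spacers=len(spacers),
        total_spacer_bp=sum(r.gap_bp for r in spacers),
        max_spacer=max_sp,
        min_spacer=min((r.gap_bp for r in spacers), default=0),
        longest_spacer_pair=sp_pair,
    )


def _signed_order(table_or_names) -> list[tuple[str, int]]:
    if isinstance(table_or_names, AnnotationTable):
        out = []
        for f in table_or_names.features:
            if f.cls is FeatureClass.CONTROL:
                continue
            out.append((f.name, -1 if f.strand is Strand.MINOR else 1))
        return out
    out = []
    for item in table_or_names:
        if isinstance(item, tuple):
            out.append((item[0], item[1]))
        else:
            name = item.strip()
            if name.startswith("-"):
                out.append((name[1:], -1))
            elif name.startswith("+"):
                out.append((name[1:], 1))
            else:
                out.append((name, 1))
    return out


def _adjacencies(order: list[tuple[str, int]], signed: bool) -> set:
    n = len(order)
    adj = set()
    for i in range(n):
        a, sa = order[i]
        b, sb = order[(i + 1) % n]
        if signed:
            # canonical under reading the circle in either direction
            fwd = (a, sa, b, sb)
            rev = (b, -sb, a, -sa)
            adj.add(min(fwd, rev))
        else:
            adj.add(frozenset((a, b)))
    return adj


def compare_order(
    observed: Union[AnnotationTable, Sequence],
    reference: Sequence,
    signed: bool = False,
) -> OrderComparison:
    """Rotation-invariant comparison of two circular gene orders.

    Control-region entries are dropped from annotation tables so the
    comparison is over genes. ``signed=True`` makes adjacencies
    strand-aware (an inversion of a block then counts as a change even when
    the unsigned neighbour sets agree).
    """
    obs = _signed_order(observed)
    ref = _signed_order(reference)
    obs_names = [g for g, _ in obs]
    ref_names = [g for g, _ in ref]
    if sorted(obs_names) != sorted(ref_names):
        diff = sorted(set(obs_names) ^ set(ref_names))
        raise MitocharError(f"gene sets differ; symmetric difference: {diff}")
    obs_adj = _adjacencies(obs, signed)
    ref_adj = _adjacencies(ref, signed)
    broken = obs_adj - ref_adj
    displaced = set()
    for a in obs_adj ^ ref_adj:
        if signed:
            displaced.update((a[0], a[2]))
        else:
            displaced.update(a)
    return OrderComparison(
        observed=tuple(obs_names),
        reference=tuple(ref_names),
        breakpoints=len(broken),
        displaced=tuple(sorted(displaced)),
    )


def ancestral_insect_order() -> list[str]:
    """The ancestral insect mitochondrial gene order (reference arrangement)."""
    text = (
        resources.files("mitochar.data")
        .joinpath("ancestral_insect_order.txt")
        .read_text()
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
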