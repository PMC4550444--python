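"""Concatenated-PCG supermatrices, pairwise distances, neighbor joining.

This stage is the desk-scale, distance-based stand-in for a full
maximum-likelihood analysis: the 13 protein-coding genes are concatenated
in a fixed canonical order, pairwise distances are computed under p, JC69
or K2P models, and a Saitou-Nei neighbor-joining tree is built with
optional nonparametric bootstrap support from column resampling. Neighbor
joining is exact on additive distance matrices, which is what the tests
exploit. Newick serialization goes through dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from mitochar.errors import MitocharError
from mitochar.mito_io import AnnotationTable, FeatureClass, Mitogenome, extract_gene_sequence

__all__ = [
    "PCG_ORDER",
    "Supermatrix",
    "DistanceMatrix",
    "PhyloTree",
    "build_supermatrix",
    "pairwise_distance",
    "nj_tree",
    "bootstrap_support",
]

#: Canonical concatenation order of the 13 protein-coding genes (genome order).
PCG_ORDER = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4L", "nad6", "cob", "nad1",
)

_PURINES = {"A", "G"}


@dataclass
class Supermatrix:
    """Aligned, concatenated per-gene blocks for a set of taxa."""

    taxa: list[str]
    sequences: list[str]  # same order as taxa, equal lengths
    blocks: dict[str, tuple[int, int]]  # gene -> [start, end) column range
    gene_order: tuple[str, ...] = PCG_ORDER

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column_subset(self, columns: np.ndarray) -> "Supermatrix":
        """Resampled matrix over the given column indices (bootstrap)."""
        seqs = []
        for s in self.sequences:
            arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            seqs.append(arr[columns].tobytes().decode("ascii"))
        return Supermatrix(
            taxa=list(self.taxa), sequences=seqs, blocks={}, gene_order=self.gene_order
        )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])


@dataclass
class PhyloTree:
    """An unrooted (or outgroup-rooted) tree with optional support labels."""

    tree: dendropy.Tree
    notes: list[str] = field(default_factory=list)

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_names(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each canonicalized as the side not
        containing the alphabetically first taxon."""
        all_taxa = self.leaf_names()
        anchor = min(all_taxa)
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = {leaf.taxon.label for leaf in node.leaf_iter()}
            side = below if anchor not in below else all_taxa - below
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(frozenset(side))
        return out


def build_supermatrix(
    genomes: Sequence[tuple[str, Mitogenome, AnnotationTable]],
    gene_order: Sequence[str] = PCG_ORDER,
) -> Supermatrix:
    """Concatenate the sense-strand PCG sequences of each genome.

    Per-gene sequences must be present for every taxon and equal in length
    across taxa (the synthetic generator guarantees this; real data must be
    pre-aligned externally). Incomplete-stop remnants (CDS length not a
    multiple of 3) are trimmed to full codons before concatenation.
    """
    if not genomes:
        raise MitocharError("no genomes given")
    per_gene: dict[str, list[str]] = {g: [] for g in gene_order}
    taxa = []
    for name, genome, table in genomes:
        taxa.append(name)
        by_name = {f.name: f for f in table.features if f.cls is FeatureClass.PCG}
        for gene in gene_order:
            if gene not in by_name:
                raise MitocharError(f"taxon {name!r} is missing gene {gene!r}")
            seq = extract_gene_sequence(genome, by_name[gene])
            seq = seq[: len(seq) - len(seq) % 3]  # trim incomplete-stop remnant
            per_gene[gene].append(seq)
    blocks: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene in gene_order:
        lens = {len(s) for s in per_gene[gene]}
        if len(lens) > 1:
            raise MitocharError(
                f"gene {gene!r} has unequal lengths across taxa {sorted(lens)}; "
                "align per-gene sequences externally first"
            )
        width = lens.pop()
        blocks[gene] = (offset, offset + width)
        offset += width
    sequences = ["".join(per_gene[g][k] for g in gene_order) for k in range(len(taxa))]
    return Supermatrix(taxa=taxa, sequences=sequences, blocks=blocks, gene_order=tuple(gene_order))


def _pair_counts(s1: str, s2: str) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions) over non-gap columns."""
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def pairwise_distance(matrix: Supermatrix, model: str = "K2P") -> DistanceMatrix:
    """Pairwise distances under the p, JC69 or K2P model.

    p is the mismatch fraction over mutually non-gap columns;
    JC69 = -(3/4) ln(1 - 4p/3); K2P = -(1/2) ln((1-2P-Q) sqrt(1-2Q)) with
    P/Q the transition/transversion proportions. Pairs whose correction is
    undefined (log of a nonpositive number) are flagged and assigned the
    maximum defined distance plus one.
    """
    if model not in ("p", "JC69", "K2P"):
        raise MitocharError(f"unknown distance model {model!r}")
    taxa = matrix.taxa
    m = len(taxa)
    d = np.zeros((m, m))
    undefined: list[tuple[str, str]] = []
    for i in range(m):
        for j in range(i + 1, m):
            n, ts, tv = _pair_counts(matrix.sequences[i], matrix.sequences[j])
            if n == 0:
                undefined.append((taxa[i], taxa[j]))
                d[i, j] = d[j, i] = math.nan
                continue
            p = (ts + tv) / n
            if model == "p":
                val = p
            elif model == "JC69":
                arg = 1.0 - 4.0 * p / 3.0
                val = -0.75 * math.log(arg) if arg > 0 else math.nan
            else:
                P, Q = ts / n, tv / n
                a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                val = (
                    -0.5 * math.log(a1 * math.sqrt(a2))
                    if a1 > 0 and a2 > 0
                    else math.nan
                )
            if math.isnan(val):
                undefined.append((taxa[i], taxa[j]))
            d[i, j] = d[j, i] = val
    if undefined:
        finite = d[np.isfinite(d)]
        fill = (finite.max() if finite.size else 1.0) + 1.0
        d[~np.isfinite(d)] = fill
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa=list(taxa), matrix=d, undefined_pairs=undefined)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined; ties are
    broken by the lexicographically smallest pair of cluster labels (a
    cluster is labelled by its alphabetically first leaf). Negative branch
    lengths are clamped to zero with a note.
    """
    n0 = len(d.taxa)
    if n0 < 3:
        raise MitocharError("neighbor joining requires at least 3 taxa")
    notes: list[str] = []

    def fmt(x: float) -> float:
        if x < 0:
            notes.append(f"negative branch length {x:.6g} clamped to 0")
            return 0.0
        return x

    # active clusters: label -> (representative leaf name, newick fragment)
    labels = list(d.taxa)
    reps = {lab: lab for lab in labels}
    frags = {lab: lab.replace(" ", "_") for lab in labels}
    dist = {
        (a, b): float(d.matrix[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def get(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    active = list(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * get(a, b) - r[a] - r[b]
                key = tuple(sorted((reps[a], reps[b])))
                cand = (q, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best  # type: ignore[misc]
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        la, lb = fmt(la), fmt(lb)
        counter += 1
        new = f"__node{counter}"
        frags[new] = f"({frags[a]}:{la:.10g},{frags[b]}:{lb:.10g})"
        reps[new] = min(reps[a], reps[b])
        for c in active:
            if c in (a, b):
                continue
            dist[(new, c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [new]
    # final three-way join (3-point formulae)
    a, b, c = sorted(active, key=lambda x: reps[x])
    la = fmt(0.5 * (get(a, b) + get(a, c) - get(b, c)))
    lb = fmt(0.5 * (get(a, b) + get(b, c) - get(a, c)))
    lc = fmt(0.5 * (get(a, c) + get(b, c) - get(a, b)))
    newick = f"({frags[a]}:{la:.10g},{frags[b]}:{lb:.10g},{frags[c]}:{lc:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return PhyloTree(tree=tree, notes=notes)


def bootstrap_support(
    matrix: Supermatrix,
    replicates: int,
    seed: int,
    model: str = "K2P",
) -> PhyloTree:
    """NJ tree with bootstrap support labels from column resampling.

    Each replicate resamples alignment columns with replacement, rebuilds
    the distance matrix and NJ tree, and support for each internal
    bipartition of the full-data tree is the percentage of replicates
    containing it. ``replicates=0`` returns the unlabeled tree.
    """
    base = nj_tree(pairwise_distance(matrix, model))
    if replicates == 0:
        return base
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in base.bipartitions()}
    ncol = matrix.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_tree(pairwise_distance(matrix.column_subset(cols), model))
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_taxa = base.leaf_names()
    anchor = min(all_taxa)
    for node in base.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if anchor not in below else all_taxa - below
        key = frozenset(side)
        if key in counts:
            node.label = str(round(100.0 * counts[key] / replicates))
    return base
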