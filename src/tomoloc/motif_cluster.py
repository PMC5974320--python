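"""Motif family construction by PWM alignment and UPGMA clustering.

Pairs of motifs are aligned ungapped at every offset with a minimum column
overlap; the similarity of an alignment is the mean per-column Pearson
correlation between the aligned probability columns, and the pair's score
is the best over offsets. Distances (1 - best correlation) feed a UPGMA
dendrogram (size-weighted arithmetic-mean linkage, merge heights = half the
merge distance, deterministic lexicographic tie-breaking). Cutting the
dendrogram at a height threshold yields motif families; each family gets a
consensus profile by aligning members to the family's widest member and
averaging the overlapping columns (a single alignment-and-average pass).

No reverse-complement alignment is performed: these are single-stranded
mRNA motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif_scan import Motif


def _column_correlation(x: np.ndarray, y: np.ndarray, pseudocount: float = 1e-3) -> float:
    """Pearson r between two probability columns (length-4 vectors).

    Zero-variance columns get a pseudocount first; if a column is still
    constant (exactly uniform), the correlation is defined as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0:
        x = x + pseudocount
    if np.ptp(y) == 0:
        y = y + pseudocount
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def pairwise_similarity(m1: Motif, m2: Motif, min_overlap: int = 4) -> tuple[float, int]:
    """Best ungapped alignment score between two motifs and its offset.

    The offset is the start of m2 relative to the start of m1 (may be
    negative). Score = max over offsets with >= min_overlap aligned columns
    of the mean per-column Pearson correlation.
    """
    p1, p2 = m1.to_pwm(), m2.to_pwm()
    w1, w2 = p1.shape[0], p2.shape[0]
    if min_overlap > min(w1, w2):
        raise ValueError(f"min_overlap {min_overlap} exceeds a motif width "
                         f"({w1}, {w2})")
    best_score, best_offset = -np.inf, 0
    for offset in range(-(w2 - min_overlap), w1 - min_overlap + 1):
        lo1, hi1 = max(0, offset), min(w1, offset + w2)
        cols = hi1 - lo1
        if cols < min_overlap:
            continue
        rs = [
            _column_correlation(p1[j], p2[j - offset])
            for j in range(lo1, hi1)
        ]
        score = float(np.mean(rs))
        if score > best_score:
            best_score, best_offset = score, offset
    return best_score, best_offset


@dataclass
class MotifDistanceMatrix:
    """Symmetric motif distance matrix: 1 - best alignment correlation."""

    ids: list[str]
    dist: np.ndarray
    offsets: np.ndarray   # best offset of column motif relative to row motif

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.isnan(self.dist).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.dist), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")


def similarity_matrix(motifs: list[Motif], min_overlap: int = 4) -> MotifDistanceMatrix:
    n = len(motifs)
    dist = np.zeros((n, n))
    offsets = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            score, off = pairwise_similarity(motifs[i], motifs[j], min_overlap)
            dist[i, j] = dist[j, i] = 1.0 - score
            offsets[i, j] = off
            offsets[j, i] = -off
    return MotifDistanceMatrix([m.id for m in motifs], dist, offsets)


@dataclass
class Dendrogram:
    """A UPGMA tree node. Leaves have height 0 and a single member."""

    members: tuple[str, ...]
    height: float = 0.0
    children: tuple["Dendrogram", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def label(self) -> str:
        return min(self.members)

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.members[0]
        parts = []
        for child in self.children:
            branch = self.height - child.height
            parts.append(f"{child._newick()}:{branch:.6g}")
        return "(" + ",".join(parts) + ")"


def upgma(d: MotifDistanceMatrix) -> Dendrogram:
    """UPGMA dendrogram of a distance matrix.

    Merge heights are half the merge distance; new distances are the
    size-weighted arithmetic mean; ties are broken by the lexicographically
    smallest (label, label) pair for determinism.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 motifs to cluster")
    if np.isnan(d.dist).any():
        raise ValueError("NaN distance")
    nodes: dict[int, Dendrogram] = {i: Dendrogram((d.ids[i],)) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): float(d.dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        # closest pair; ties resolved by the sorted labels of the two clusters
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((nodes[kv[0][0]].label,
                                                 nodes[kv[0][1]].label)))),
        )
        (i, j), dij = best
        merged = Dendrogram(
            members=tuple(sorted(nodes[i].members + nodes[j].members)),
            height=dij / 2.0,
            children=(nodes[i], nodes[j]),
        )
        size_new = sizes[i] + sizes[j]
        new_dist = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dist[k] = (sizes[i] * dik + sizes[j] * djk) / size_new
        del nodes[i], nodes[j], sizes[i], sizes[j]
        dist = {key: v for key, v in dist.items() if i not in key and j not in key}
        nodes[next_id] = merged
        sizes[next_id] = size_new
        for k, v in new_dist.items():
            dist[tuple(sorted((k, next_id)))] = v
        next_id += 1
    return next(iter(nodes.values()))


@dataclass
class MotifFamily:
    """A family of similar motifs with its averaged consensus profile."""

    member_ids: list[str]
    merge_height: float
    consensus_pwm: np.ndarray | None = None


def cut_families(tree: Dendrogram, height_threshold: float) -> list[MotifFamily]:
    """Maximal subtrees merging at height <= threshold become families."""
    if height_threshold < 0:
        raise ValueError("threshold must be >= 0")
    families: list[MotifFamily] = []

    def visit(node: Dendrogram) -> None:
        if node.height <= height_threshold:
            families.append(MotifFamily(sorted(node.members), node.height))
        else:
            for child in node.children:
                visit(child)

    visit(tree)
    return families


def familial_consensus(members: list[Motif], min_overlap: int = 4) -> np.ndarray:
    """Averaged PWM of a motif family.

    Members are aligned (pairwise best offset) to the family's widest
    member; column probabilities are averaged over the members covering each
    column and renormalized. Columns not covered by any aligned member keep
    the anchor's probabilities.
    """
    if not members:
        raise ValueError("empty family")
    if len(members) == 1:
        return members[0].to_pwm()
    anchor = max(members, key=lambda m: m.width)
    offsets = {}
    lo, hi = 0, anchor.width
    for m in members:
        if m is anchor:
            offsets[id(m)] = 0
            continue
        _, off = pairwise_similarity(anchor, m, min_overlap=min(min_overlap, m.width))
        offsets[id(m)] = off
        lo = min(lo, off)
        hi = max(hi, off + m.width)
    width = hi - lo
    acc = np.zeros((width, 4))
    cover = np.zeros(width)
    for m in members:
        off = offsets[id(m)] - lo
        pwm = m.to_pwm()
        acc[off:off + m.width] += pwm
        cover[off:off + m.width] += 1
    covered = cover > 0
    acc[covered] /= cover[covered, None]
    acc = acc[covered]
    return acc / acc.sum(axis=1, keepdims=True)


def cluster_motifs(
    motifs: list[Motif],
    min_overlap: int = 4,
    height_threshold: float | None = None,
) -> tuple[MotifDistanceMatrix, Dendrogram, list[MotifFamily] | None]:
    """Distance matrix + dendrogram (+ families if a threshold is given)."""
    dmat = similarity_matrix(motifs, min_overlap)
    tree = upgma(dmat)
    families = None
    if height_threshold is not None:
        families = cut_families(tree, height_threshold)
        by_id = {m.id: m for m in motifs}
        for fam in families:
            fam.consensus_pwm = familial_consensus(
                [by_id[i] for i in fam.member_ids], min_overlap)
    return dmat, tree, families


def family_table(families: list[MotifFamily]) -> pd.DataFrame:
    rows = [
        {"family": i + 1, "motif": m, "merge_height": fam.merge_height,
         "n_members": len(fam.member_ids)}
        for i, fam in enumerate(families)
        for m in fam.member_ids
    ]
    return pd.DataFrame(rows)
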