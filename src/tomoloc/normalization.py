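"""Whole-egg normalization of section counts and fraction profiles.

Sequencing counts from axial egg sections cannot be normalized with the
standard equal-distribution assumption (most genes ARE differentially
distributed along the axis), so per-segment size factors are anchored on a
small panel of genes whose true axial distribution is measured
independently by RT-qPCR tomography. For each anchor the qPCR fraction
profile (from efficiency**(-Cq)) is divided by its RNA-seq fraction
profile; the per-segment median over anchors, rescaled to geometric mean 1,
is the size factor. Factors are computed and applied per replicate.

Also provides the low-expression filter (mean normalized read >= 15 kept),
the conversion of normalized counts to per-gene fraction profiles, and the
global-mean normalization used for the 4-segment proteome intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CqTable, SegmentTable

log = logging.getLogger(__name__)


@dataclass
class SizeFactors:
    """Per-(segment, replicate) multiplicative size factors.

    ``data`` is segments x replicates; each replicate column has geometric
    mean 1 (canonical scaling).
    """

    data: pd.DataFrame   # index: segments, columns: replicate numbers

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError("size factors must be positive")

    def factor(self, segment: str, rep: int) -> float:
        return float(self.data.loc[segment, rep])


@dataclass
class FractionProfiles:
    """Per-gene segment fraction profiles, per replicate and consensus.

    Each row of every frame sums to 1. The consensus is the arithmetic mean
    of the available replicate fraction vectors, renormalized, so replicates
    weigh equally regardless of sequencing depth.
    """

    replicates: dict[int, pd.DataFrame]
    consensus: pd.DataFrame
    molecule_kind: str


def cq_to_fractions(cq: CqTable, anchor: str) -> np.ndarray:
    """Relative axial distribution of one anchor from its Cq values.

    Relative quantity per segment is efficiency**(-Cq); each replicate is
    normalized to sum 1 (so constant plate offsets cancel) before averaging
    across replicates. Returns a fraction vector over segments summing to 1.
    """
    if anchor not in cq.data.index:
        raise ValueError(f"anchor {anchor!r} not in Cq table")
    eff = cq.efficiency.get(anchor, 2.0)
    if eff <= 1.0:
        raise ValueError(f"anchor {anchor!r}: efficiency {eff} must be > 1")
    per_rep = []
    for rep in cq.replicates:
        cq_vec = cq.replicate_frame(rep).loc[anchor].to_numpy(dtype=float)
        if np.isnan(cq_vec).any():
            raise ValueError(f"anchor {anchor!r}: missing Cq in replicate {rep}")
        q = eff ** (-cq_vec)
        per_rep.append(q / q.sum())
    frac = np.mean(per_rep, axis=0)
    return frac / frac.sum()


def _cq_replicate_fractions(cq: CqTable, anchor: str, rep: int) -> np.ndarray:
    eff = cq.efficiency.get(anchor, 2.0)
    if eff <= 1.0:
        raise ValueError(f"anchor {anchor!r}: efficiency {eff} must be > 1")
    cq_vec = cq.replicate_frame(rep).loc[anchor].to_numpy(dtype=float)
    if np.isnan(cq_vec).any():
        raise ValueError(f"anchor {anchor!r}: missing Cq in replicate {rep}")
    q = eff ** (-cq_vec)
    return q / q.sum()


def compute_size_factors(rnaseq: SegmentTable, cq: CqTable,
                         anchors: list[str] | None = None) -> SizeFactors:
    """Anchor-based per-segment size factors (median over anchors).

    For each anchor g and replicate: ratio_s = qPCR fraction / RNA-seq
    fraction; factor_s = median over anchors, rescaled so the geometric mean
    over segments is 1. Anchors with a zero count in any segment are
    excluded with a warning.
    """
    if anchors is None:
        anchors = cq.anchor_ids
    if rnaseq.segments != cq.segments:
        raise ValueError("segment labels of counts and Cq table differ")
    if len(cq.replicates) not in (1, len(rnaseq.replicates)):
        raise ValueError("Cq table must have 1 replicate or match the counts")
    factors = {}
    for rep in rnaseq.replicates:
        cq_rep = rep if len(cq.replicates) > 1 else cq.replicates[0]
        counts = rnaseq.replicate_frame(rep)
        ratios = []
        for anchor in anchors:
            if anchor not in counts.index:
                raise ValueError(f"anchor {anchor!r} not present in count table")
            c = counts.loc[anchor].to_numpy(dtype=float)
            if (c <= 0).any() or np.isnan(c).any():
                log.warning("anchor %s excluded in replicate %s (zero/missing count)",
                            anchor, rep)
                continue
            r = c / c.sum()
            q = _cq_replicate_fractions(cq, anchor, cq_rep)
            ratios.append(q / r)
        if not ratios:
            raise ValueError(f"no usable anchor in replicate {rep}")
        raw = np.median(np.vstack(ratios), axis=0)
        factors[rep] = raw / stats.gmean(raw)
    return SizeFactors(pd.DataFrame(factors, index=rnaseq.segments))


def apply_size_factors(counts: SegmentTable, f: SizeFactors) -> SegmentTable:
    """Multiply each (segment, replicate) column by its size factor."""
    if list(f.data.index) != counts.segments:
        raise ValueError("segment labels of counts and size factors differ")
    data = counts.data.copy()
    for rep in counts.replicates:
        if rep not in f.data.columns:
            raise ValueError(f"no size factors for replicate {rep}")
        for seg in counts.segments:
            data[f"{seg}_r{rep}"] = data[f"{seg}_r{rep}"] * f.factor(seg, rep)
    return counts.copy_with(data)


def filter_low_expression(norm: SegmentTable, threshold: float = 15.0) -> SegmentTable:
    """Keep genes whose mean normalized value over all cells is >= threshold.

    Genes averaging strictly below the threshold are considered too lowly
    expressed to be quantified reliably and are removed.
    """
    means = norm.data.mean(axis=1, skipna=True)
    keep = means >= threshold
    removed = int((~keep).sum())
    if removed:
        log.info("expression filter removed %d/%d genes (mean < %g)",
                 removed, len(keep), threshold)
    if keep.sum() == 0:
        log.warning("expression filter removed every gene")
    return norm.copy_with(norm.data.loc[keep])


def to_fractions(norm: SegmentTable) -> FractionProfiles:
    """Per-replicate and consensus fraction profiles of each gene.

    Replicates in which a gene has zero (or missing) total are dropped for
    that gene with a warning; the consensus is the renormalized mean of the
    remaining replicate fraction vectors.
    """
    per_rep: dict[int, pd.DataFrame] = {}
    stacks = []
    for rep in norm.replicates:
        frame = norm.replicate_frame(rep)
        totals = frame.sum(axis=1, skipna=False)
        ok = totals > 0
        n_bad = int((~ok).sum())
        if n_bad:
            log.warning("replicate %s: dropped %d genes with zero/missing total",
                        rep, n_bad)
        frac = frame.loc[ok].div(totals[ok], axis=0)
        per_rep[rep] = frac
        stacks.append(frac)
    combined = pd.concat(stacks, keys=norm.replicates)
    consensus = combined.groupby(level=1, sort=False).mean()
    consensus = consensus.div(consensus.sum(axis=1), axis=0)
    consensus = consensus.loc[[g for g in norm.gene_ids if g in consensus.index]]
    return FractionProfiles(per_rep, consensus, norm.molecule_kind)


def global_mean_normalize(protein: SegmentTable) -> SegmentTable:
    """Divide every sample column by its mean over proteins.

    After normalization all (segment, replicate) columns have mean 1,
    removing inter-sample loading variation ("global mean" normalization of
    proteome intensities).
    """
    means = protein.data.mean(axis=0, skipna=True)
    if (means == 0).any() or means.isna().any():
        bad = means.index[(means == 0) | means.isna()][0]
        raise ValueError(f"sample column {bad!r} has zero mean")
    return protein.copy_with(protein.data.div(means, axis=1))
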