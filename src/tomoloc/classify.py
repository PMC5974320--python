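"""Rule-based localization classification of axial profiles.

RNA profiles over five segments A-E (animal pole -> vegetal pole) are
assigned one of five categories by published inequality rules on the
gene's transcript fractions:

* extremely_animal: maximum in A; (A+B) > (D+E); C > D or C > E
* animal:           maximum in B; D+E < 40% of all transcripts
* vegetal:          (D+E) > (A+B+C); D > A or D > B or D > C
* extremely_vegetal: E > 50% of all transcripts; E > 2*D
* other:            none of the above

"Maximum in X" means strictly greater than every other segment; ties fail
the rule. The rule sets are pairwise mutually exclusive except
{vegetal, extremely_vegetal}; precedence extremely_vegetal ->
extremely_animal -> vegetal -> animal resolves that pair, so every profile
receives exactly one label.

Protein profiles over four segments A-D use: animal (A strict max and
A - D > 0.05), even (all fractions in [0.20, 0.30] with relative standard
deviation < 5%, or B strict max with C > D), vegetal (C or D strict max
and max(C, D) - A > 0.05), precedence animal -> even -> vegetal -> other.
Proteins are classified per replicate with a 2-of-3 quorum consensus.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RNA_CATEGORIES = ["extremely_animal", "animal", "vegetal", "extremely_vegetal", "other"]
PROTEIN_CATEGORIES = ["animal", "even", "vegetal", "other"]


def _validate(p: np.ndarray, n_seg: int, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != n_seg:
        raise ValueError(f"expected {n_seg} fractions, got {p.shape[-1]}")
    if (p < 0).any():
        raise ValueError("negative fraction")
    sums = p.sum(axis=-1)
    if np.max(np.abs(sums - 1.0)) > tol:
        raise ValueError("fractions do not sum to 1")
    return p


def rna_rule_matrix(p: np.ndarray) -> np.ndarray:
    """Boolean (n, 4) matrix: which of the four named RNA rule sets fire.

    Columns follow RNA_CATEGORIES[:4]. Input is (n, 5) fractions.
    """
    p = np.atleast_2d(p)
    a, b, c, d, e = (p[:, i] for i in range(5))
    max_a = (a > b) & (a > c) & (a > d) & (a > e)
    max_b = (b > a) & (b > c) & (b > d) & (b > e)
    extremely_animal = max_a & (a + b > d + e) & ((c > d) | (c > e))
    animal = max_b & (d + e < 0.40)
    vegetal = (d + e > a + b + c) & ((d > a) | (d > b) | (d > c))
    extremely_vegetal = (e > 0.50) & (e > 2.0 * d)
    return np.column_stack([extremely_animal, animal, vegetal, extremely_vegetal])


def classify_rna_array(p: np.ndarray, validate: bool = True) -> np.ndarray:
    """Vectorized RNA classification of an (n, 5) fraction array."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if validate:
        _validate(p, 5)
    rules = rna_rule_matrix(p)
    labels = np.full(len(p), "other", dtype=object)
    # precedence: extreme categories first (extremely_vegetal profiles also
    # satisfy the vegetal rules; the categories are reported disjoint)
    for name, col in [("animal", 1), ("vegetal", 2),
                      ("extremely_animal", 0), ("extremely_vegetal", 3)]:
        labels[rules[:, col]] = name
    return labels


def classify_rna(fractions) -> str:
    """Localization category of one five-segment RNA fraction profile."""
    return str(classify_rna_array(np.asarray(fractions, dtype=float))[0])


def protein_rule_matrix(p: np.ndarray) -> np.ndarray:
    """Boolean (n, 3) matrix of the animal/even/vegetal protein rules."""
    p = np.atleast_2d(p)
    a, b, c, d = (p[:, i] for i in range(4))
    max_a = (a > b) & (a > c) & (a > d)
    max_b = (b > a) & (b > c) & (b > d)
    cd = np.maximum(c, d)
    max_cd = (cd > a) & (cd > b)
    animal = max_a & (a - d > 0.05)
    mean = p.mean(axis=1)
    sd = p.std(axis=1, ddof=1)
    rsd = np.divide(sd, mean, out=np.full_like(sd, np.inf), where=mean > 0) * 100.0
    in_band = ((p >= 0.20) & (p <= 0.30)).all(axis=1)
    even = (in_band & (rsd < 5.0)) | (max_b & (c > d))
    vegetal = max_cd & (cd - a > 0.05)
    return np.column_stack([animal, even, vegetal])


def classify_protein_array(p: np.ndarray, validate: bool = True) -> np.ndarray:
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if validate:
        _validate(p, 4)
    rules = protein_rule_matrix(p)
    labels = np.full(len(p), "other", dtype=object)
    # precedence animal -> even -> vegetal: later assignments win, so apply
    # in reverse precedence order
    for name, col in [("vegetal", 2), ("even", 1), ("animal", 0)]:
        labels[rules[:, col]] = name
    return labels


def classify_protein(fractions) -> str:
    """Localization category of one four-segment protein fraction profile."""
    return str(classify_protein_array(np.asarray(fractions, dtype=float))[0])


def _label_kind(label: str) -> str:
    if label in ("extremely_animal", "extremely_vegetal"):
        return "rna"
    if label == "even":
        return "protein"
    return "either"


def consensus_category(labels: list[str], min_agree: int = 2) -> str:
    """Label shared by >= min_agree replicates; 'other' if no quorum."""
    if not labels:
        raise ValueError("no labels")
    kinds = {_label_kind(lb) for lb in labels}
    if "rna" in kinds and "protein" in kinds:
        raise ValueError(f"mixed RNA and protein labels: {labels}")
    label, count = Counter(labels).most_common(1)[0]
    return label if count >= min_agree else "other"


@dataclass
class ClassificationSummary:
    """Per-category counts and proportions for one classified gene set."""

    counts: pd.Series
    proportions: pd.Series
    labels: pd.Series
    molecule_kind: str

    @property
    def n_genes(self) -> int:
        return int(self.counts.sum())


def summarize(labels: dict[str, str] | pd.Series, molecule_kind: str) -> ClassificationSummary:
    """Category counts/proportions in a stable category order."""
    labels = pd.Series(labels, dtype=object)
    order = RNA_CATEGORIES if molecule_kind == "rna" else PROTEIN_CATEGORIES
    if len(labels) == 0:
        log.warning("summarize: empty label set")
        counts = pd.Series(0, index=order, dtype=int)
        return ClassificationSummary(counts, counts.astype(float), labels, molecule_kind)
    unknown = set(labels) - set(order)
    if unknown:
        raise ValueError(f"labels {unknown} not valid for {molecule_kind}")
    counts = labels.value_counts().reindex(order, fill_value=0).astype(int)
    return ClassificationSummary(counts, counts / counts.sum(), labels, molecule_kind)


def classify_table(
    profiles,
    molecule_kind: str,
    per_replicate: bool | None = None,
    min_agree: int = 2,
) -> pd.Series:
    """Classify a FractionProfiles object into per-gene consensus labels.

    RNA is classified on the consensus fraction profile by default;
    ``per_replicate=True`` classifies each replicate and takes the quorum
    consensus instead. Proteins always use per-replicate + quorum (the
    replicate-consensus rule is stated for proteins).
    """
    if per_replicate is None:
        per_replicate = molecule_kind == "protein"
    classify_array = (classify_rna_array if molecule_kind == "rna"
                      else classify_protein_array)
    if not per_replicate:
        frame = profiles.consensus
        return pd.Series(classify_array(frame.to_numpy()), index=frame.index)
    per_rep = {rep: pd.Series(classify_array(f.to_numpy()), index=f.index)
               for rep, f in profiles.replicates.items()}
    all_genes = profiles.consensus.index
    out = {}
    for g in all_genes:
        labels = [s.loc[g] for s in per_rep.values() if g in s.index]
        out[g] = consensus_category(labels, min_agree=min_agree)
    return pd.Series(out)
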