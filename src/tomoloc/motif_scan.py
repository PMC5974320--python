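"""Motif occurrence scanning in 3'UTR sequences.

Implements FIMO-style scanning of short cis-regulatory motifs ("zipcodes",
e.g. the CAC-rich vegetal localization elements) against 3'UTR sequences in
two modes:

* **IUPAC mode** -- the motif is a degenerate consensus string (e.g.
  ``[TA][TC]CAC``); a window matches iff every base is in the allowed set.
* **PWM mode** -- the motif is a position weight matrix; windows are scored
  by log-odds against a background composition and called at a score
  threshold corresponding to an exact match p-value, computed by dynamic
  programming over the discretized null score distribution.

Scanning is forward-strand only: the substrate is single-stranded mRNA, so
no reverse-complement matches are considered anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DNA = "ACGT"
_CODE = {b: i for i, b in enumerate(DNA)}

#: IUPAC degenerate nucleotide code -> set of admitted DNA bases.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_SETS.items()}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _CODE.items():
        codes[arr == ord(base)] = i
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def parse_consensus(text: str) -> str:
    """Normalize a consensus motif string to one IUPAC letter per column.

    Accepts plain IUPAC strings and the bracket dialect used in the
    localization-motif literature (``[UA][UC]CAC``). RNA alphabet (U) is
    converted to DNA (T).
    """
    text = text.strip().upper().replace("U", "T")
    if not re.fullmatch(r"(\[[A-Z]+\]|[A-Z])+", text):
        raise ValueError(f"malformed motif consensus {text!r}")
    out = []
    for token in re.findall(r"\[[A-Z]+\]|[A-Z]", text):
        if token.startswith("["):
            bases = set()
            for ch in token[1:-1]:
                if ch not in IUPAC_SETS:
                    raise ValueError(f"unknown IUPAC symbol {ch!r} in {text!r}")
                bases.update(IUPAC_SETS[ch])
            out.append(_SET_TO_IUPAC[frozenset(bases)])
        else:
            if token not in IUPAC_SETS:
                raise ValueError(f"unknown IUPAC symbol {token!r} in {text!r}")
            out.append(token)
    if not out:
        raise ValueError("empty motif consensus")
    return "".join(out)


@dataclass
class Motif:
    """A localization-motif definition: IUPAC consensus and/or PWM.

    ``pwm`` is a (width, 4) array of per-column base probabilities in ACGT
    order, each row summing to 1.
    """

    id: str
    consensus: str | None = None
    pwm: np.ndarray | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError(f"motif {self.id}: needs a consensus or a PWM")
        if self.consensus is not None:
            self.consensus = parse_consensus(self.consensus)
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError(f"motif {self.id}: PWM must be (width, 4)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"motif {self.id}: PWM rows must sum to 1")

    @property
    def width(self) -> int:
        if self.pwm is not None:
            return self.pwm.shape[0]
        return len(self.consensus)  # type: ignore[arg-type]

    def to_pwm(self) -> np.ndarray:
        """PWM representation; IUPAC columns become uniform over the set."""
        if self.pwm is not None:
            return self.pwm
        w = len(self.consensus)  # type: ignore[arg-type]
        pwm = np.zeros((w, 4))
        for j, letter in enumerate(self.consensus):  # type: ignore[arg-type]
            allowed = IUPAC_SETS[letter]
            for b in allowed:
                pwm[j, _CODE[b]] = 1.0 / len(allowed)
        return pwm

    def iupac_consensus(self, threshold: float = 0.25) -> str:
        """Degenerate consensus: per column, bases with probability >= threshold."""
        if self.pwm is None:
            return self.consensus  # type: ignore[return-value]
        letters = []
        for row in self.pwm:
            bases = frozenset(DNA[i] for i in range(4) if row[i] >= threshold)
            if not bases:
                bases = frozenset(DNA[int(np.argmax(row))])
            letters.append(_SET_TO_IUPAC[bases])
        return "".join(letters)


@dataclass
class MotifOccurrence:
    """One located motif match on the forward strand (0-based start)."""

    gene_id: str | None
    start: int
    matched: str
    score: float
    p: float | None = None


# ---------------------------------------------------------------------------
# IUPAC scanning
# ---------------------------------------------------------------------------

def _allowed_table(consensus: str) -> np.ndarray:
    """(width, 4) boolean table of admitted bases per motif column."""
    ok = np.zeros((len(consensus), 4), dtype=bool)
    for j, letter in enumerate(consensus):
        for b in IUPAC_SETS[letter]:
            ok[j, _CODE[b]] = True
    return ok


def scan_iupac(utr: str, motif: Motif, gene_id: str | None = None) -> list[MotifOccurrence]:
    """All forward-strand windows compatible with the motif's IUPAC consensus.

    Overlapping hits are all reported. The occurrence score is the motif
    width (every IUPAC match is equally good).
    """
    consensus = motif.iupac_consensus()
    w = len(consensus)
    if w > len(utr):
        return []
    codes = encode(utr)
    ok = _allowed_table(consensus)
    n_win = len(utr) - w + 1
    valid = np.ones(n_win, dtype=bool)
    for j in range(w):
        valid &= ok[j][codes[j:j + n_win]]
    return [
        MotifOccurrence(gene_id, int(i), utr[i:i + w], float(w))
        for i in np.nonzero(valid)[0]
    ]


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------

@dataclass
class PwmScoreDistribution:
    """Exact null distribution of a PWM's window log-odds score.

    Scores are log2(p_col(base)/background(base)) with a small pseudocount,
    discretized on an integer grid of ``step`` bits, and convolved column by
    column under the background model (the standard exact-p-value DP used by
    FIMO-class scanners).
    """

    score_int: np.ndarray      # (width, 4) integer scores on the grid
    step: float
    offset: int                # grid index of the minimal possible total
    tail: np.ndarray           # tail[i] = P(total_int >= offset + i)
    pmf: np.ndarray            # pmf[i] = P(total_int == offset + i)

    def pvalue_int(self, total: int) -> float:
        i = total - self.offset
        if i < 0:
            return 1.0
        if i >= len(self.tail):
            return 0.0
        return float(self.tail[i])

    def pvalue(self, score: float) -> float:
        return self.pvalue_int(int(round(score / self.step)))

    def threshold(self, alpha: float) -> float:
        """Smallest attainable score whose tail probability is <= alpha."""
        idx = np.nonzero((self.tail <= alpha) & (self.pmf > 0))[0]
        if len(idx) == 0:
            # even the best word is more probable than alpha: nothing passes
            return (self.offset + len(self.tail)) * self.step
        return float((self.offset + idx[0]) * self.step)


def pwm_score_distribution(
    motif: Motif,
    background: np.ndarray | None = None,
    step: float = 1e-3,
    pseudocount: float = 1e-4,
) -> PwmScoreDistribution:
    pwm = motif.to_pwm()
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")
    bg = background + pseudocount
    bg = bg / bg.sum()
    scores = np.log2((pwm + pseudocount) / bg[None, :])
    score_int = np.round(scores / step).astype(np.int64)

    # iterative convolution of per-column score mass under the background
    pmf = np.array([1.0])
    pmf_lo = 0
    for j in range(score_int.shape[0]):
        col_lo = int(score_int[j].min())
        col_hi = int(score_int[j].max())
        col = np.zeros(col_hi - col_lo + 1)
        for b in range(4):
            col[score_int[j, b] - col_lo] += background[b]
        pmf = np.convolve(pmf, col)
        pmf_lo += col_lo
    tail = np.cumsum(pmf[::-1])[::-1]
    return PwmScoreDistribution(score_int=score_int, step=step, offset=pmf_lo,
                                tail=tail, pmf=pmf)


def pwm_pvalue_threshold(
    motif: Motif,
    background: np.ndarray | None = None,
    alpha: float = 0.001,
    step: float = 1e-3,
    pseudocount: float = 1e-4,
) -> float:
    """Score threshold whose exact null tail probability is <= ``alpha``."""
    return pwm_score_distribution(motif, background, step, pseudocount).threshold(alpha)


def scan_pwm(
    utr: str,
    motif: Motif,
    threshold: float,
    background: np.ndarray | None = None,
    gene_id: str | None = None,
    step: float = 1e-3,
    pseudocount: float = 1e-4,
    dist: PwmScoreDistribution | None = None,
) -> list[MotifOccurrence]:
    """Forward-strand windows scoring >= threshold, with exact p-values."""
    if dist is None:
        dist = pwm_score_distribution(motif, background, step, pseudocount)
    w = dist.score_int.shape[0]
    if w > len(utr):
        return []
    codes = encode(utr)
    n_win = len(utr) - w + 1
    totals = np.zeros(n_win, dtype=np.int64)
    for j in range(w):
        totals += dist.score_int[j][codes[j:j + n_win]]
    thr_int = int(round(threshold / dist.step))
    hits = np.nonzero(totals >= thr_int)[0]
    return [
        MotifOccurrence(gene_id, int(i), utr[i:i + w],
                        float(totals[i] * dist.step), dist.pvalue_int(int(totals[i])))
        for i in hits
    ]


# ---------------------------------------------------------------------------
# Category-level summaries
# ---------------------------------------------------------------------------

def scan_motif(
    utrs: dict[str, str],
    motif: Motif,
    mode: str = "iupac",
    alpha: float = 0.001,
    background: np.ndarray | None = None,
) -> list[MotifOccurrence]:
    """Scan one motif against a set of UTRs in either mode."""
    if mode == "iupac":
        return [occ for g, s in utrs.items() for occ in scan_iupac(s, motif, g)]
    if mode == "pwm":
        dist = pwm_score_distribution(motif, background)
        thr = dist.threshold(alpha)
        return [
            occ for g, s in utrs.items()
            for occ in scan_pwm(s, motif, thr, background, g, dist=dist)
        ]
    raise ValueError(f"unknown scan mode {mode!r}")


def presence_summary(
    utrs_by_category: dict[str, dict[str, str]],
    motifs: list[Motif],
    mode: str = "iupac",
    alpha: float = 0.001,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per (motif, category): genes with >= 1 hit and occurrence density.

    This is the heatmap source: ``proportion`` is the share of the
    category's 3'UTRs containing at least one motif copy, ``occ_per_kbp``
    the total occurrence count per kilobase of category UTR sequence.
    """
    rows = []
    for cat, utrs in utrs_by_category.items():
        if not utrs:
            raise ValueError(f"category {cat!r} has no UTRs")
        total_nt = sum(len(s) for s in utrs.values())
        for motif in motifs:
            occs = scan_motif(utrs, motif, mode=mode, alpha=alpha, background=background)
            genes_hit = {o.gene_id for o in occs}
            rows.append({
                "motif": motif.id,
                "category": cat,
                "n_genes": len(utrs),
                "n_with_hit": len(genes_hit),
                "proportion": len(genes_hit) / len(utrs),
                "occ_per_kbp": len(occs) / total_nt * 1000.0,
            })
    return pd.DataFrame(rows)


def fisher_enrichment(
    a_with: int, a_without: int, b_with: int, b_without: int
) -> tuple[float, float]:
    """One-sided Fisher's exact enrichment of hits in group a vs group b.

    Returns (odds ratio, p). The odds ratio uses the Haldane correction
    (+0.5 per cell) whenever a cell is zero so it stays finite.
    """
    cells = [a_with, a_without, b_with, b_without]
    if any(c < 0 for c in cells):
        raise ValueError("negative cell count")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    table = np.array([[a_with, a_without], [b_with, b_without]])
    _, p = stats.fisher_exact(table, alternative="greater")
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)
    else:
        a, b, c, d = cells
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def position_map(
    utr: str,
    motifs: list[Motif],
    mode: str = "iupac",
    alpha: float = 0.001,
    background: np.ndarray | None = None,
) -> dict[str, list[int]]:
    """Sorted occurrence start positions per motif for one UTR (plot source)."""
    out: dict[str, list[int]] = {}
    for motif in motifs:
        occs = scan_motif({"": utr}, motif, mode=mode, alpha=alpha, background=background)
        out[motif.id] = sorted(o.start for o in occs)
    return out
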