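"""K-mer over-representation statistics in 3'UTR sets.

For a localization category with n genes, a k-mer's observed count O_g in
each gene's 3'UTR (overlapping windows, forward strand) is compared with
its expectation under an equiprobable-base model,

    E_g = C(N_g - t*(k-1), t) / 4**(t*k)

(C the binomial coefficient; with the default repeat parameter t=1 this is
(N_g - k + 1) / 4**k), via the goodness-of-fit statistic

    x2 = sum_g (O_g - E_g)**2 / E_g,   df = n - 1,

tested upper-tailed. A k-mer is called over-represented when p < alpha
(default 0.001, no multiple-testing correction) AND the total observed
count exceeds the total expected count. Significant k-mers exclusive to one
category ("unique") are cross-referenced against discovered motif
consensus sequences.

Caveats (documented, by design): overlapping windows are not independent,
so the nominal chi-squared null is approximate; df = n - 1 treats genes as
cells of a goodness-of-fit table even though E_g varies between genes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motif_scan import DNA, Motif, encode, IUPAC_SETS

log = logging.getLogger(__name__)


def kmer_index(kmer: str) -> int:
    code = 0
    for ch in kmer:
        if ch not in DNA:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer")
        code = code * 4 + DNA.index(ch)
    return code


def index_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(DNA[code % 4])
        code //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(DNA, repeat=k)]


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every overlapping k-window."""
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[j:j + n_win]
    return out


def count_kmers(seq: str, k: int) -> dict[str, int]:
    """Counts of all observed k-mers (overlapping windows, forward strand)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = encode(seq)
    wins = _window_codes(codes, k)
    if len(wins) == 0:
        return {}
    uniq, counts = np.unique(wins, return_counts=True)
    return {index_to_kmer(int(u), k): int(c) for u, c in zip(uniq, counts)}


def count_matrix(seqs: dict[str, str], k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """(genes x 4**k observed-count matrix, per-gene length array).

    Genes shorter than k are excluded (logged).
    """
    rows, lengths, ids = [], [], []
    for gene, seq in seqs.items():
        codes = encode(seq)
        if len(codes) < k:
            log.info("gene %s (length %d) excluded from k=%d statistic",
                     gene, len(codes), k)
            continue
        wins = _window_codes(codes, k)
        rows.append(np.bincount(wins, minlength=4 ** k))
        lengths.append(len(codes))
        ids.append(gene)
    if not rows:
        return pd.DataFrame(np.empty((0, 4 ** k), dtype=np.int64)), np.empty(0, dtype=int)
    mat = pd.DataFrame(np.vstack(rows), index=ids)
    return mat, np.asarray(lengths)


def expected_count(N: int, k: int, t: int = 1, A: int = 4) -> float:
    """Expected k-mer count in a random sequence of length N.

    E = C(N - t*(k-1), t) / A**(t*k); for t=1 this is (N - k + 1) / A**k.
    Returns 0 (with a warning) when the sequence is too short.
    """
    top = N - t * (k - 1)
    if top < t:
        log.warning("sequence length %d too short for k=%d, t=%d: E=0", N, k, t)
        return 0.0
    return math.comb(top, t) / A ** (t * k)


@dataclass
class KmerModel:
    """Chi-squared over-representation result for one k-mer in one category."""

    kmer: str
    n: int                       # genes contributing (N_g >= k)
    sum_obs: float
    sum_exp: float
    x2: float
    df: int
    p: float
    alpha: float = 0.001

    @property
    def significant(self) -> bool:
        return self.p < self.alpha and self.sum_obs > self.sum_exp


def kmer_chi2(utrs: dict[str, str], kmer: str, t: int = 1,
              alpha: float = 0.001) -> KmerModel:
    """Upper-tailed chi-squared over-representation test of one k-mer."""
    k = len(kmer)
    target = kmer_index(kmer)
    obs, exp = [], []
    for gene, seq in utrs.items():
        codes = encode(seq)
        if len(codes) < k:
            log.info("gene %s excluded from k=%d statistic", gene, k)
            continue
        e = expected_count(len(codes), k, t)
        if e == 0:
            continue
        wins = _window_codes(codes, k)
        obs.append(int((wins == target).sum()))
        exp.append(e)
    n = len(obs)
    if n < 2:
        raise ValueError(f"need >= 2 usable genes, got {n}")
    obs_arr, exp_arr = np.asarray(obs, float), np.asarray(exp, float)
    if (exp_arr == 0).all():
        raise ValueError("all expected counts are zero")
    x2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = n - 1
    p = float(stats.chi2.sf(x2, df))
    return KmerModel(kmer, n, float(obs_arr.sum()), float(exp_arr.sum()),
                     x2, df, p, alpha)


def overrepresented_kmers(utrs: dict[str, str], k: int,
                          alpha: float = 0.001) -> pd.DataFrame:
    """Test all 4**k k-mers at once; returns the full statistics table.

    Columns: kmer, sum_obs, sum_exp, x2, df, p, significant. Raw p < alpha
    is used (no multiple-testing correction) plus the over-representation
    requirement sum_obs > sum_exp.
    """
    if not utrs:
        raise ValueError("empty UTR category")
    mat, lengths = count_matrix(utrs, k)
    n = len(lengths)
    if n < 2:
        raise ValueError(f"need >= 2 usable genes, got {n}")
    O = mat.to_numpy(dtype=float)                     # (n, 4^k)
    E = (lengths - k + 1) / 4.0 ** k                  # (n,)
    # sum_g (O - E)^2 / E = sum O^2/E - 2*sum O + sum E  (vectorized per k-mer)
    x2 = (O ** 2 / E[:, None]).sum(axis=0) - 2 * O.sum(axis=0) + E.sum()
    df = n - 1
    p = stats.chi2.sf(x2, df)
    sum_obs = O.sum(axis=0)
    sum_exp = np.full(4 ** k, E.sum())
    out = pd.DataFrame({
        "kmer": all_kmers(k),
        "sum_obs": sum_obs,
        "sum_exp": sum_exp,
        "x2": x2,
        "df": df,
        "p": p,
    })
    out["significant"] = (out["p"] < alpha) & (out["sum_obs"] > out["sum_exp"])
    return out


def significant_set(stats_table: pd.DataFrame) -> set[str]:
    return set(stats_table.loc[stats_table["significant"], "kmer"])


def unique_kmers(significant_animal: set[str],
                 significant_vegetal: set[str]) -> tuple[set[str], set[str]]:
    """K-mers significant in exactly one of the two category groups."""
    lengths = {len(s) for s in significant_animal | significant_vegetal}
    if len(lengths) > 1:
        raise ValueError(f"mixed k-mer lengths: {sorted(lengths)}")
    return (significant_animal - significant_vegetal,
            significant_vegetal - significant_animal)


def kmer_in_motif(kmer: str, motif: Motif, pwm_threshold: float = 0.25) -> bool:
    """True iff some length-k window of the motif consensus accepts the k-mer.

    PWM motifs are reduced to a degenerate IUPAC consensus (bases with
    probability >= pwm_threshold per column).
    """
    consensus = motif.iupac_consensus(threshold=pwm_threshold)
    k = len(kmer)
    if k > len(consensus):
        return False
    for start in range(len(consensus) - k + 1):
        window = consensus[start:start + k]
        if all(base in IUPAC_SETS[sym] for base, sym in zip(kmer, window)):
            return True
    return False


def crossref_motifs(kmers, motifs) -> dict[str, list[str]]:
    """Map each k-mer to the motifs whose consensus contains it."""
    motif_list = getattr(motifs, "motifs", motifs)
    return {
        kmer: [m.id for m in motif_list if kmer_in_motif(kmer, m)]
        for kmer in kmers
    }


def enrichment_table(
    animal_utrs: dict[str, str],
    vegetal_utrs: dict[str, str],
    ks=range(3, 8),
    alpha: float = 0.001,
    motifs=None,
) -> pd.DataFrame:
    """Per-k summary of over-represented / unique / motif-matched k-mer counts.

    The animal group is the extremely-animal 3'UTR set; the vegetal group is
    the union of the vegetal and extremely vegetal sets.
    """
    rows = []
    for k in ks:
        sig_a = significant_set(overrepresented_kmers(animal_utrs, k, alpha))
        sig_v = significant_set(overrepresented_kmers(vegetal_utrs, k, alpha))
        uniq_a, uniq_v = sig_a - sig_v, sig_v - sig_a
        row = {
            "k": k,
            "animal_overrepresented": len(sig_a),
            "animal_unique": len(uniq_a),
            "vegetal_overrepresented": len(sig_v),
            "vegetal_unique": len(uniq_v),
        }
        if motifs is not None:
            xref_a = crossref_motifs(uniq_a, motifs)
            xref_v = crossref_motifs(uniq_v, motifs)
            row["animal_unique_in_motifs"] = sum(bool(v) for v in xref_a.values())
            row["vegetal_unique_in_motifs"] = sum(bool(v) for v in xref_v.values())
        rows.append(row)
    return pd.DataFrame(rows)


def null_rejection_rate(
    n_reps: int,
    n_genes: int,
    length: int,
    kmer: str,
    alpha: float = 0.001,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo type-I error of the k-mer test under iid uniform sequences.

    Simulates ``n_reps`` categories of ``n_genes`` uniform-random sequences
    of the given length and reports the fraction in which the fixed k-mer is
    called significant. Because overlapping windows are dependent, the
    empirical rate deviates from the nominal alpha; this utility quantifies
    that deviation.
    """
    if rng is None:
        rng = np.random.default_rng()
    k = len(kmer)
    target = kmer_index(kmer)
    E = expected_count(length, k)
    df = n_genes - 1
    rejections = 0
    chunk = max(1, int(2e7 // (n_genes * length)))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        codes = rng.integers(0, 4, size=(m * n_genes, length), dtype=np.int8)
        wins = np.zeros((m * n_genes, length - k + 1), dtype=np.int64)
        for j in range(k):
            wins = wins * 4 + codes[:, j:j + length - k + 1]
        O = (wins == target).sum(axis=1).reshape(m, n_genes)
        x2 = ((O - E) ** 2 / E).sum(axis=1)
        p = stats.chi2.sf(x2, df)
        sig = (p < alpha) & (O.sum(axis=1) > n_genes * E)
        rejections += int(sig.sum())
        done += m
    return rejections / n_reps
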