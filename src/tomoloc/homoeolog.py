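"""Homoeologous gene-pair analysis for the allotetraploid genome.

Xenopus laevis retains duplicated gene copies from its two ancestral
subgenomes, annotated with ``.L`` (long chromosome) and ``.S`` (short
chromosome) suffixes. This module pairs L/S copies by their shared base
symbol, compares their localization categories (concordance), flags
diametrically opposite pairs (one copy vegetal/extremely vegetal, the
other animal/extremely animal), and counts localization-motif occurrences
(e.g. TTCAC, TGCAC) in each copy's 3'UTR.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .motif_scan import Motif, scan_iupac

log = logging.getLogger(__name__)

VEGETAL_SIDE = {"vegetal", "extremely_vegetal"}
ANIMAL_SIDE = {"animal", "extremely_animal"}

_DEFAULT_SUFFIX = re.compile(r"^(?P<base>.+)\.(?P<sub>[LS])$")


@dataclass
class HomoeologPair:
    """A matched .L/.S gene pair with localization comparison flags."""

    base_symbol: str
    gene_L: str
    gene_S: str
    category_L: str | None = None
    category_S: str | None = None

    @property
    def concordant(self) -> bool:
        return (self.category_L is not None
                and self.category_L == self.category_S)

    @property
    def opposite(self) -> bool:
        cats = {self.category_L, self.category_S}
        return (bool(cats & VEGETAL_SIDE) and bool(cats & ANIMAL_SIDE))


def pair_homoeologs(
    gene_ids,
    suffix_pattern: str | re.Pattern = _DEFAULT_SUFFIX,
) -> tuple[list[HomoeologPair], list[str]]:
    """Match L/S copies by base symbol; returns (pairs, unpaired ids).

    The default suffix grammar is the Xenbase ``.L``/``.S`` convention; an
    alternative regex with ``base`` and ``sub`` groups may be supplied.
    """
    pattern = re.compile(suffix_pattern)
    copies: dict[str, dict[str, str]] = {}
    unpaired: list[str] = []
    no_suffix: list[str] = []
    for gid in gene_ids:
        m = pattern.match(gid)
        if not m:
            no_suffix.append(gid)
            continue
        base, sub = m.group("base"), m.group("sub")
        slot = copies.setdefault(base, {})
        if sub in slot:
            raise ValueError(f"base symbol {base!r} has two .{sub} entries")
        slot[sub] = gid
    pairs = []
    for base in sorted(copies):
        slot = copies[base]
        if "L" in slot and "S" in slot:
            pairs.append(HomoeologPair(base, slot["L"], slot["S"]))
        else:
            unpaired.extend(slot.values())
    return pairs, sorted(unpaired) + sorted(no_suffix)


def annotate_categories(
    pairs: list[HomoeologPair],
    labels: dict[str, str] | pd.Series,
) -> tuple[list[HomoeologPair], list[HomoeologPair]]:
    """Attach categories; pairs with an unclassified member are set aside.

    Returns (classified pairs, unpairable pairs). A member missing from the
    label map (e.g. removed by the expression filter) makes the pair
    unpairable; it is reported, not silently dropped.
    """
    labels = dict(labels)
    classified, unpairable = [], []
    for pair in pairs:
        cat_l, cat_s = labels.get(pair.gene_L), labels.get(pair.gene_S)
        pair.category_L, pair.category_S = cat_l, cat_s
        if cat_l is None or cat_s is None:
            log.warning("pair %s excluded: unclassified member", pair.base_symbol)
            unpairable.append(pair)
        else:
            classified.append(pair)
    return classified, unpairable


@dataclass
class ConcordanceSummary:
    """Concordance of localization categories within homoeologue pairs."""

    n_pairs: int
    n_concordant: int
    fraction_concordant: float
    discordant: list[HomoeologPair]
    opposite: list[HomoeologPair]
    contingency: pd.DataFrame   # L categories x S categories


def concordance(pairs: list[HomoeologPair]) -> ConcordanceSummary:
    """Fraction of pairs whose copies share a category, plus flags."""
    if not pairs:
        raise ValueError("no classified pairs")
    for pair in pairs:
        if pair.category_L is None or pair.category_S is None:
            raise ValueError(f"pair {pair.base_symbol} has an unclassified member")
    n_conc = sum(p.concordant for p in pairs)
    discordant = [p for p in pairs if not p.concordant]
    opposite = [p for p in pairs if p.opposite]
    table = pd.crosstab(
        pd.Series([p.category_L for p in pairs], name="L"),
        pd.Series([p.category_S for p in pairs], name="S"),
    )
    return ConcordanceSummary(
        n_pairs=len(pairs),
        n_concordant=n_conc,
        fraction_concordant=n_conc / len(pairs),
        discordant=discordant,
        opposite=opposite,
        contingency=table,
    )


def pair_motif_counts(
    pairs: list[HomoeologPair],
    utrs: dict[str, str],
    motifs: list[Motif | str],
) -> pd.DataFrame:
    """Occurrence counts of each motif in the L and S 3'UTRs of each pair.

    Motifs may be IUPAC strings or Motif objects. When the two copies have
    different categories, the ratio is reported vegetal-side copy first
    ("count_vegetal_copy:count_other_copy"). Missing UTRs are flagged with
    NaN counts.
    """
    motif_objs = [m if isinstance(m, Motif) else Motif(id=m, consensus=m)
                  for m in motifs]
    rows = []
    for pair in pairs:
        utr_l, utr_s = utrs.get(pair.gene_L), utrs.get(pair.gene_S)
        if utr_l is None or utr_s is None:
            log.warning("pair %s: missing UTR", pair.base_symbol)
        for motif in motif_objs:
            n_l = len(scan_iupac(utr_l, motif)) if utr_l is not None else None
            n_s = len(scan_iupac(utr_s, motif)) if utr_s is not None else None
            ratio = None
            if (n_l is not None and n_s is not None
                    and pair.category_L != pair.category_S):
                if pair.category_S in VEGETAL_SIDE and pair.category_L not in VEGETAL_SIDE:
                    ratio = f"{n_s}:{n_l}"
                else:
                    ratio = f"{n_l}:{n_s}"
            rows.append({
                "base_symbol": pair.base_symbol,
                "motif": motif.id,
                "category_L": pair.category_L,
                "category_S": pair.category_S,
                "count_L": n_l,
                "count_S": n_s,
                "vegetal_to_other_ratio": ratio,
            })
    return pd.DataFrame(rows)


def pairs_table(pairs: list[HomoeologPair]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "base_symbol": p.base_symbol,
            "gene_L": p.gene_L,
            "gene_S": p.gene_S,
            "category_L": p.category_L,
            "category_S": p.category_S,
            "concordant": p.concordant,
            "opposite": p.opposite,
        }
        for p in pairs
    ])
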