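"""Synthetic data generator emulating axial egg-tomography studies.

Generates every input the pipeline consumes, with known ground truth, so
each stage can be validated end to end without external downloads:

* RNA count tables: five segments (A-E, animal pole first), three
  biological replicates. Genes are drawn from the four localization
  archetypes plus "other" in the study's observed proportions (2.8%
  extremely animal, 94.4% animal, 1.3% vegetal, 0.2% extremely vegetal);
  per-gene true fraction vectors are Dirichlet draws around the archetype,
  rejection-sampled until they satisfy their own category's rules, so the
  generating category is exact by construction. Counts are negative
  binomial around abundance x fraction x per-segment library distortion.
* Anchor genes with qPCR Cq tables (Cq = const - log2(fraction) + noise);
  a noise-free mode supports exact size-factor recovery experiments.
* Protein intensity tables: four segments, log-normal noise.
* 3'UTR FASTA sets with category-dependent planted motifs (e.g. TTCAC at a
  Poisson per-UTR rate in vegetal genes), plant positions recorded.
* Homoeologous .L/.S pairs with a designed discordant fraction; S copies
  share the L background UTR mutated at a per-base rate, with motif
  planting following each copy's own category.

All randomness flows from a single seed; identical config + seed
reproduces every table exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import classify_protein, classify_rna
from .io_formats import CqTable, SegmentTable, UtrSet, RNA_SEGMENTS, PROTEIN_SEGMENTS

DNA = "ACGT"

#: Archetype fraction vectors chosen to sit safely inside each rule region.
RNA_ARCHETYPES: dict[str, tuple[float, ...]] = {
    "extremely_animal": (0.42, 0.28, 0.15, 0.10, 0.05),
    "animal": (0.22, 0.38, 0.20, 0.12, 0.08),
    "vegetal": (0.10, 0.10, 0.15, 0.35, 0.30),
    "extremely_vegetal": (0.05, 0.05, 0.10, 0.15, 0.65),
    "other": (0.20, 0.20, 0.20, 0.20, 0.20),
}

PROTEIN_ARCHETYPES: dict[str, tuple[float, ...]] = {
    "animal": (0.40, 0.25, 0.20, 0.15),
    "even": (0.25, 0.26, 0.25, 0.24),
    "vegetal": (0.15, 0.20, 0.25, 0.40),
    "other": (0.28, 0.24, 0.24, 0.24),
}

#: Observed mRNA category shares (remainder goes to "other").
RNA_PROPORTIONS = {
    "extremely_animal": 0.028,
    "animal": 0.944,
    "vegetal": 0.013,
    "extremely_vegetal": 0.002,
    "other": 0.013,
}

PROTEIN_PROPORTIONS = {
    "animal": 0.094,
    "even": 0.431,
    "vegetal": 0.223,
    "other": 0.252,
}

#: Anchor panel mirroring a 10-assay qPCR tomography design spanning the
#: categories (2 vegetal, 2 animal, 2 extremely vegetal, 3 extremely
#: animal, 1 ubiquitous).
ANCHOR_PANEL = [
    "vegetal", "vegetal", "animal", "animal",
    "extremely_vegetal", "extremely_vegetal",
    "extremely_animal", "extremely_animal", "extremely_animal", "other",
]


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    seed: int = 0
    # RNA counts
    n_genes: int = 2000
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(RNA_PROPORTIONS))
    archetypes: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(RNA_ARCHETYPES))
    dirichlet_concentration: float = 200.0
    abundance_meanlog: float = math.log(2000.0)
    abundance_sdlog: float = 1.0
    nb_dispersion: float = 200.0      # negative-binomial size parameter
    segment_distortion: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    n_replicates: int = 3
    # anchors / qPCR
    n_anchors: int = 10
    anchor_abundance: float = 5000.0
    cq_sigma: float = 0.2             # cycles of technical qPCR noise
    cq_base: float = 18.0
    noise_free_anchors: bool = False
    # protein
    n_proteins: int = 500
    protein_proportions: dict[str, float] = field(
        default_factory=lambda: dict(PROTEIN_PROPORTIONS))
    protein_archetypes: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(PROTEIN_ARCHETYPES))
    protein_noise_sd: float = 0.05    # log-normal multiplicative noise (log scale)
    protein_abundance_meanlog: float = 2.0
    protein_abundance_sdlog: float = 1.0
    # 3'UTRs
    utr_meanlog: float = 6.8          # median ~900 nt
    utr_sdlog: float = 0.45
    utr_min_length: int = 50
    base_composition: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    motif_plant: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "TTCAC": {"vegetal": 2.0, "extremely_vegetal": 2.0},
    })
    # homoeologues
    pair_fraction: float = 0.30       # fraction of base genes duplicated to .L/.S
    discordant_fraction: float = 0.03
    s_mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        for cat, vec in self.archetypes.items():
            got = classify_rna(vec)
            if got != cat:
                raise ValueError(
                    f"RNA archetype for {cat!r} classifies as {got!r}")
        for cat, vec in self.protein_archetypes.items():
            got = classify_protein(vec)
            if got != cat:
                raise ValueError(
                    f"protein archetype for {cat!r} classifies as {got!r}")
        if abs(sum(self.category_proportions.values()) - 1) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if not 0 <= self.pair_fraction <= 1:
            raise ValueError("pair_fraction must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Designed truth serialized alongside every generated dataset."""

    categories: dict[str, str]
    fractions: pd.DataFrame               # gene x segments (true fractions)
    anchors: list[str] = field(default_factory=list)
    pair_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    designed_discordant: list[str] = field(default_factory=list)
    motif_positions: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    @property
    def designed_concordance(self) -> float | None:
        if not self.pair_map:
            return None
        return 1.0 - len(self.designed_discordant) / len(self.pair_map)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "categories": self.categories,
            "fractions": {g: list(map(float, row))
                          for g, row in self.fractions.iterrows()},
            "anchors": self.anchors,
            "pair_map": {k: list(v) for k, v in self.pair_map.items()},
            "designed_discordant": self.designed_discordant,
            "motif_positions": self.motif_positions,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _category_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n genes."""
    quotas = {c: n * p for c, p in proportions.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = n - sum(counts.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _draw_fractions(category: str, archetypes: dict, concentration: float,
                    classify, rng: np.random.Generator,
                    max_tries: int = 1000) -> np.ndarray:
    """Dirichlet draw around the archetype, rejected until it classifies back."""
    alpha = np.asarray(archetypes[category], float) * concentration
    for _ in range(max_tries):
        frac = rng.dirichlet(alpha)
        if classify(frac) == category:
            return frac
    raise RuntimeError(f"could not draw an in-region profile for {category!r}")


def _nb_sample(mu: np.ndarray, size: float, rng: np.random.Generator) -> np.ndarray:
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(float)


def _roster(config: SynthConfig, rng: np.random.Generator) -> dict[str, str]:
    counts = _category_counts(config.n_genes, config.category_proportions)
    categories: dict[str, str] = {}
    i = 0
    for cat in config.category_proportions:
        for _ in range(counts.get(cat, 0)):
            i += 1
            categories[f"g{i:05d}"] = cat
    return categories


def simulate_roster(config: SynthConfig,
                    rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the gene roster: categories and true fraction profiles only."""
    if rng is None:
        rng = config.rng()
    categories = _roster(config, rng)
    fractions = pd.DataFrame(
        [
            _draw_fractions(cat, config.archetypes,
                            config.dirichlet_concentration, classify_rna, rng)
            for cat in categories.values()
        ],
        index=list(categories), columns=RNA_SEGMENTS)
    return GroundTruth(categories=categories, fractions=fractions)


def simulate_rna(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> tuple[SegmentTable, CqTable, GroundTruth]:
    """Simulate the RNA count table, the anchor Cq table and ground truth.

    When an existing ``truth`` (with categories/fractions, e.g. after the
    homoeologue step) is passed, counts are generated for that roster;
    otherwise a fresh roster is drawn.
    """
    if rng is None:
        rng = config.rng()
    d = np.asarray(config.segment_distortion, float)
    if len(d) != 5:
        raise ValueError("segment_distortion must have 5 entries")
    if truth is None:
        categories = _roster(config, rng)
        fractions = pd.DataFrame(
            [
                _draw_fractions(cat, config.archetypes,
                                config.dirichlet_concentration,
                                classify_rna, rng)
                for cat in categories.values()
            ],
            index=list(categories), columns=RNA_SEGMENTS)
        truth = GroundTruth(categories=categories, fractions=fractions)
    categories, fractions = truth.categories, truth.fractions

    gene_ids = [g for g in categories if g not in truth.anchors]
    abundance = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog,
                              size=len(gene_ids))
    frac = fractions.loc[gene_ids].to_numpy()
    mu = abundance[:, None] * frac * d[None, :]          # (genes, 5)
    cols = {}
    for r, rep in enumerate(range(1, config.n_replicates + 1)):
        counts = _nb_sample(mu, config.nb_dispersion, rng)
        for s, seg in enumerate(RNA_SEGMENTS):
            cols[f"{seg}_r{rep}"] = counts[:, s]
    data = pd.DataFrame(cols, index=gene_ids)

    # anchors: archetype-exact true fractions, high abundance
    anchor_ids, anchor_rows, cq_rows = [], [], []
    for i in range(config.n_anchors):
        cat = ANCHOR_PANEL[i % len(ANCHOR_PANEL)]
        aid = f"anchor{i + 1:02d}"
        anchor_ids.append(aid)
        afrac = np.asarray(config.archetypes[cat], float)
        categories[aid] = cat
        truth.fractions.loc[aid] = afrac
        amu = config.anchor_abundance * afrac * d
        row = {}
        cq_row = {}
        for rep in range(1, config.n_replicates + 1):
            if config.noise_free_anchors:
                counts = np.tile(amu, 1)
                noise = np.zeros(5)
            else:
                counts = _nb_sample(np.tile(amu, (1, 1)), config.nb_dispersion,
                                    rng)[0]
                noise = rng.normal(0.0, config.cq_sigma, size=5)
            plate_offset = 0.0 if config.noise_free_anchors else rng.normal(0, 0.5)
            for s, seg in enumerate(RNA_SEGMENTS):
                row[f"{seg}_r{rep}"] = counts[s]
                cq_row[f"{seg}_r{rep}"] = (config.cq_base - np.log2(afrac[s])
                                           + plate_offset + noise[s])
        anchor_rows.append(row)
        cq_rows.append(cq_row)

    if anchor_ids:
        data = pd.concat([data, pd.DataFrame(anchor_rows, index=anchor_ids)])
    truth.anchors = anchor_ids
    reps = list(range(1, config.n_replicates + 1))
    table = SegmentTable(data, list(RNA_SEGMENTS), reps, "rna")
    cq = CqTable(pd.DataFrame(cq_rows, index=anchor_ids), list(RNA_SEGMENTS), reps)
    return table, cq, truth


def simulate_protein(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SegmentTable, dict[str, str]]:
    """Four-segment protein intensity table with log-normal noise."""
    if rng is None:
        rng = config.rng()
    counts = _category_counts(config.n_proteins, config.protein_proportions)
    ids, cats, fracs = [], {}, []
    i = 0
    for cat in config.protein_proportions:
        for _ in range(counts.get(cat, 0)):
            i += 1
            pid = f"p{i:05d}"
            ids.append(pid)
            cats[pid] = cat
            fracs.append(_draw_fractions(cat, config.protein_archetypes,
                                         config.dirichlet_concentration,
                                         classify_protein, rng))
    frac = np.asarray(fracs)
    abundance = rng.lognormal(config.protein_abundance_meanlog,
                              config.protein_abundance_sdlog, size=len(ids))
    cols = {}
    for rep in range(1, config.n_replicates + 1):
        noise = rng.lognormal(0.0, config.protein_noise_sd, size=frac.shape)
        vals = abundance[:, None] * frac * noise
        for s, seg in enumerate(PROTEIN_SEGMENTS):
            cols[f"{seg}_r{rep}"] = vals[:, s]
    data = pd.DataFrame(cols, index=ids)
    reps = list(range(1, config.n_replicates + 1))
    return SegmentTable(data, list(PROTEIN_SEGMENTS), reps, "protein"), cats


def simulate_homoeologs(
    config: SynthConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Introduce .L/.S pairs into a roster (before count/UTR generation).

    A fraction of base genes is duplicated: the original becomes the .L
    copy; the .S copy gets its own in-region fraction draw from the same
    category, except for a designed discordant subset,
    round(discordant_fraction x n_pairs) pairs, whose .S copy is
    re-assigned to a different category and its profile re-drawn there.
    """
    if rng is None:
        rng = config.rng()
    base_ids = [g for g in truth.categories if g not in truth.anchors]
    n_pairs = int(round(config.pair_fraction * len(base_ids)))
    chosen = sorted(rng.choice(len(base_ids), size=n_pairs, replace=False))
    n_disc = int(round(config.discordant_fraction * n_pairs))
    disc_idx = set(rng.choice(n_pairs, size=n_disc, replace=False).tolist())

    all_cats = list(config.category_proportions)
    categories = dict(truth.categories)
    fractions = truth.fractions.copy()
    pair_map: dict[str, tuple[str, str]] = {}
    discordant: list[str] = []
    for rank, idx in enumerate(chosen):
        base = base_ids[idx]
        cat_l = categories.pop(base)
        frac_l = fractions.loc[base]
        fractions = fractions.drop(index=base)
        gid_l, gid_s = f"{base}.L", f"{base}.S"
        categories[gid_l] = cat_l
        fractions.loc[gid_l] = frac_l
        if rank in disc_idx:
            cat_s = all_cats[rng.integers(0, len(all_cats))]
            while cat_s == cat_l:
                cat_s = all_cats[rng.integers(0, len(all_cats))]
            discordant.append(base)
        else:
            cat_s = cat_l
        categories[gid_s] = cat_s
        fractions.loc[gid_s] = _draw_fractions(
            cat_s, config.archetypes, config.dirichlet_concentration,
            classify_rna, rng)
        pair_map[base] = (gid_l, gid_s)
    return GroundTruth(categories=categories, fractions=fractions,
                       anchors=list(truth.anchors), pair_map=pair_map,
                       designed_discordant=sorted(discordant))


def _random_seq(length: int, comp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=length, p=comp)


def _plant_motif(codes: np.ndarray, motif_codes: np.ndarray, n_copies: int,
                 occupied: np.ndarray, rng: np.random.Generator,
                 max_tries: int = 200) -> list[int]:
    """Overwrite n_copies of the motif at non-overlapping random positions."""
    w = len(motif_codes)
    positions: list[int] = []
    n_valid = len(codes) - w + 1
    if n_valid <= 0:
        return positions
    for _ in range(n_copies):
        for _ in range(max_tries):
            start = int(rng.integers(0, n_valid))
            if not occupied[start:start + w].any():
                codes[start:start + w] = motif_codes
                occupied[start:start + w] = True
                positions.append(start)
                break
    return sorted(positions)


def simulate_utrs(
    config: SynthConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> UtrSet:
    """3'UTR set with category-dependent planted motifs; positions recorded.

    Homoeologous .S copies reuse the .L background sequence mutated at the
    configured per-base rate; planting then follows each copy's own
    category, so discordant pairs acquire asymmetric motif content.
    """
    if rng is None:
        rng = config.rng()
    comp = np.asarray(config.base_composition, float)
    comp = comp / comp.sum()
    motif_codes = {
        m: np.array([DNA.index(b) for b in m.upper().replace("U", "T")])
        for m in config.motif_plant
    }
    s_of_pair = {l: s for (l, s) in truth.pair_map.values()}

    gene_ids = [g for g in truth.categories if g not in truth.anchors]
    records: dict[str, str] = {}
    plants: dict[str, dict[str, list[int]]] = {}

    def build(gene: str, background: np.ndarray) -> None:
        codes = background.copy()
        occupied = np.zeros(len(codes), dtype=bool)
        gene_plants: dict[str, list[int]] = {}
        cat = truth.categories[gene]
        for m, rates in config.motif_plant.items():
            rate = rates.get(cat, 0.0)
            n = int(rng.poisson(rate)) if rate > 0 else 0
            if n:
                gene_plants[m] = _plant_motif(codes, motif_codes[m], n,
                                              occupied, rng)
        records[gene] = "".join(DNA[c] for c in codes)
        if gene_plants:
            plants[gene] = gene_plants

    for gene in gene_ids:
        if gene.endswith(".S") and gene[:-2] in truth.pair_map:
            continue  # built together with its .L partner
        length = max(config.utr_min_length,
                     int(rng.lognormal(config.utr_meanlog, config.utr_sdlog)))
        background = _random_seq(length, comp, rng)
        build(gene, background)
        partner = s_of_pair.get(gene)
        if partner is not None:
            mutated = background.copy()
            flip = rng.random(length) < config.s_mutation_rate
            shift = rng.integers(1, 4, size=int(flip.sum()))
            mutated[flip] = (mutated[flip] + shift) % 4
            build(partner, mutated)

    truth.motif_positions = plants
    return UtrSet(records, {g: truth.categories[g] for g in records})


def simulate_dataset(
    config: SynthConfig,
) -> tuple[SegmentTable, CqTable, UtrSet, GroundTruth]:
    """Full dataset: roster -> homoeologue pairs -> counts + Cq -> UTRs."""
    rng = config.rng()
    truth = simulate_roster(config, rng)
    if config.pair_fraction > 0:
        truth = simulate_homoeologs(config, truth, rng)
    counts, cq, truth = simulate_rna(config, rng, truth)
    utrs = simulate_utrs(config, truth, rng)
    return counts, cq, utrs, truth
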