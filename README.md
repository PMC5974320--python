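# tomoloc

Axial localization analysis of biomolecule tomography profiles in the
*Xenopus laevis* egg.

The amphibian egg is polarized along its animal–vegetal (A–V) axis:
cryosectioning eggs into pooled segments (five for RNA, A–E from the
animal pole; four for protein, A–D) and quantifying each segment yields a
spatial profile per gene. `tomoloc` implements the computational half of
such a study:

* **qPCR-anchored normalization** — standard RNA-seq normalization assumes
  most genes are equally distributed between samples, which is false for
  intracellular localization. Instead, a panel of anchor genes measured
  independently by RT-qPCR tomography pins the section counts to whole-egg
  relative amounts: for anchor *g* and segment *s*, the ratio of its qPCR
  fraction (from efficiency^(−Cq)) to its RNA-seq fraction gives a
  per-segment size factor (median over anchors, geometric mean 1), and a
  low-expression filter removes genes with mean normalized reads < 15.
* **Rule-based localization classification** of fraction profiles
  p_A…p_E: *extremely animal* (max in A; A+B > D+E; C > D or E), *animal*
  (max in B; D+E < 40%), *vegetal* (D+E > A+B+C; D > A, B or C),
  *extremely vegetal* (E > 50%; E > 2·D), else *other*; protein rules for
  four segments with a 2-of-3 replicate quorum.
* **3′UTR k-mer over-representation** — for each k-mer (k = 3…7), observed
  counts per gene are tested against the random-sequence expectation
  E = (N−k+1)/4^k with the goodness-of-fit statistic
  x² = Σ_g (O_g−E_g)²/E_g, df = n−1, upper-tailed at p < 0.001, plus
  uniqueness filtering between the animal and vegetal UTR groups and
  cross-referencing against discovered motif consensi.
* **Motif scanning** (IUPAC and PWM modes with exact p-values by dynamic
  programming), per-category presence proportions, Fisher's exact
  enrichment, and **UPGMA motif-family clustering** from ungapped
  PWM alignments scored by column Pearson correlation.
* **Homoeologue analysis** — pairing .L/.S gene copies of the
  allotetraploid genome, concordance of their localization categories, and
  per-copy counts of vegetal zipcode motifs such as UUCAC/UGCAC.
* A **synthetic-data generator** that emulates the study design (archetype
  profiles in observed proportions, negative-binomial counts, anchor Cq
  tables, planted 3′UTR motifs, homoeologue pairs with a designed
  discordant fraction) with full ground truth, so every stage is testable.

## Worked example

```python
from tomoloc import (SynthConfig, simulate_dataset, compute_size_factors,
                     apply_size_factors, filter_low_expression, to_fractions,
                     classify_table, summarize)
from tomoloc.homoeolog import pair_homoeologs, annotate_categories, concordance

cfg = SynthConfig(seed=42)                      # 2000 genes, 3 replicates
counts, cq, utrs, truth = simulate_dataset(cfg)
factors = compute_size_factors(counts, cq)      # anchored size factors
kept = filter_low_expression(apply_size_factors(counts, factors))
labels = classify_table(to_fractions(kept), "rna").drop(truth.anchors)
print(summarize(labels, "rna").counts.to_string())

pairs, _ = pair_homoeologs(list(labels.index))
classified, _ = annotate_categories(pairs, labels)
s = concordance(classified)
print(f"pairs: {s.n_pairs}  concordant: {s.fraction_concordant:.3f}  "
      f"opposite: {len(s.opposite)}")
```

prints

```
extremely_animal       91
animal               2420
vegetal                39
extremely_vegetal       9
other                  40
pairs: 600  concordant: 0.960  opposite: 11
```

The category counts follow the designed proportions (the vast majority of
maternal mRNAs are animally localized; a few percent carry extreme or
vegetal profiles), and the homoeologue concordance is close to the
designed 97% — the small deficit is classification noise hitting either
member of a pair.

The same stages are available from the shell:

```bash
tomoloc simulate --seed 42 --out sim/
tomoloc normalize --counts sim/counts.tsv --cq sim/cq.tsv --out norm
tomoloc classify --fractions norm.fractions.tsv --kind rna --out cls
tomoloc run-all --seed 42 --out run/      # everything + JSON run report
```

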