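# Methods

## Normalization model

Section counts from an axial tomography experiment violate the central
assumption of standard RNA-seq normalization (equal distribution of most
genes across samples): along the egg's animal–vegetal axis, *most* genes
are differentially distributed. The package therefore anchors the counts
on genes whose axial distribution is measured independently by RT-qPCR
tomography.

For anchor *g*, segment *s*, replicate *r*: the relative qPCR quantity is
`eff_g^(−Cq_{g,s,r})` with amplification efficiency `eff_g ∈ (1, 2]`
(default 2.0). Each replicate's quantity vector is normalized to sum 1
before averaging, so constant per-plate Cq offsets cancel. The size
factor of segment *s* in replicate *r* is the **median over anchors** of
(qPCR fraction / RNA-seq fraction), rescaled so the factors' geometric
mean is 1 per replicate; the median makes one bad anchor harmless.
Factors are computed and applied per replicate (the alternative —
pooling replicates — was open; per-replicate is chosen because qPCR and
sequencing replicates come from the same egg blocks in the emulated
design).

The low-expression filter removes genes whose mean normalized value over
all segment×replicate cells is strictly below 15. Fraction profiles are
computed per replicate (each summing to 1); the consensus profile is the
renormalized arithmetic mean of replicate fraction vectors, so replicates
weigh equally regardless of depth. Protein intensities are normalized by
dividing each sample column by its mean over proteins ("global mean"
normalization); no quantile step.

## Classification rules

RNA rules operate on the five segment fractions with strict inequalities
("maximum in X" fails on ties, pushing degenerate flat profiles to
*other*); "C > D or E" is the disjunction (C > D) ∨ (C > E), and likewise
for "D > A or B or C". The five rule sets are pairwise mutually exclusive
except {vegetal, extremely vegetal} (provable from the inequalities:
*animal* needs D+E < 0.4 while *vegetal* needs D+E > 0.5, etc.);
precedence extremely vegetal → extremely animal → vegetal → animal →
other resolves that single overlap, so every profile gets exactly one
label. RNA is classified on the consensus profile by default (a flag
switches to per-replicate classification with quorum consensus); protein
is always classified per replicate with a ≥2-of-3 quorum, *other* when no
quorum. The protein "difference > 5%" is 0.05 on the fraction scale, and
RSD is the sample standard deviation (ddof = 1) over the four fractions
divided by their mean, × 100.

## K-mer statistic and its calibration

Expected counts use the equiprobable-base model
`E = C(N − t(k−1), t) / 4^(tk)` with the repeat parameter t = 1 by
default (then E = (N−k+1)/4^k); the binomial-coefficient form supports
t > 1 but is unexercised beyond unit tests. Significance requires both
p < α (raw, α = 0.001, no multiple-testing correction — a deliberate
caveat retained from the emulated protocol) and over-representation
ΣO > ΣE, since a two-sided test would also flag depletion. Genes shorter
than k are excluded from that k's statistic (logged); df = n−1 treats
genes as cells of a goodness-of-fit table even though E_g varies — kept
as printed in the protocol being emulated.

The chi-squared null is approximate in two ways, quantified by the
package's own Monte-Carlo calibration (`null_rejection_rate`, 10,000
replicates of 20 iid uniform 300-nt sequences, k = 5): overlapping
windows are dependent, and with small per-gene expectations (E ≈ 0.29)
the statistic is lumpy and right-skewed. The empirical type-I rate at
nominal α = 0.001 is ≈ 0.03 — roughly 30× anticonservative in this
regime. Down-stream conclusions in the validation experiments rely on
planted signals far above this inflated floor (planted TTCAC reaches
x² ≫ the 0.001 quantile), and the uniqueness filter subtracts the two
groups' false-positive sets from each other.

At the emulated planting rate (Poisson 2 copies per ~1-kb UTR, 150
vegetal vs 330 animal UTRs), the planted 5-mer and its two 4-mer
sub-k-mers are recovered essentially always; the 3-mer sub-k-mers are
genuinely underpowered (expected ≈ 15.6 copies per gene dwarf the +2
planted shift) — mirroring the emulated study's own finding that 3-mers
discriminate poorly between groups.

## Motif scanning

Scanning is forward-strand only everywhere (single-stranded mRNA; no
reverse complement). IUPAC mode accepts a window iff every base is in the
column's degenerate set; overlapping hits all count (this affects
occurrences-per-kbp, not presence proportions). PWM mode scores windows
by log2(p_col(base)/background(base)) with pseudocount 1e-4, discretized
on a 1e-3-bit grid; the exact null score distribution is built by
convolving per-column score masses under the background (uniform by
default), and the match threshold is the smallest attainable score whose
tail probability is ≤ α (0.001). Fisher's exact enrichment is one-sided
(hypergeometric upper tail); odds ratios use the Haldane +0.5 correction
when a cell is zero.

## Motif clustering

Pairs of motifs are aligned ungapped at every offset with ≥ 4 overlapping
columns; the alignment score is the mean per-column Pearson correlation
between probability columns (zero-variance columns get a 1e-3
pseudocount; exactly-uniform pairs define r = 0), and the pair score is
the best over offsets. UPGMA on distances 1 − score uses size-weighted
arithmetic-mean linkage, merge heights of half the merge distance, and
deterministic lexicographic tie-breaking. Families are the maximal
subtrees merging at or below a user-chosen height threshold — the
emulated study grouped motifs manually from the dendrogram, so no default
threshold claims to reproduce its family count. The familial consensus is
a single alignment-and-average pass onto the family's widest member
(iterative refinement of the profile is deliberately not re-implemented).

## Synthetic data generator

The generator emulates the study design: 5 RNA segments × 3 replicates,
RNA categories in the observed proportions (2.8% extremely animal, 94.4%
animal, 1.3% vegetal, 0.2% extremely vegetal, remainder other) at a
desk-scale default of 2000 genes; 4 protein segments with protein
proportions 9.4/43.1/22.3/25.2%.

Per-gene true fractions are Dirichlet draws (concentration 200) around
archetype vectors chosen to sit safely inside each rule region —
extremely animal (0.42, 0.28, 0.15, 0.10, 0.05), animal (0.22, 0.38,
0.20, 0.12, 0.08), vegetal (0.10, 0.10, 0.15, 0.35, 0.30), extremely
vegetal (0.05, 0.05, 0.10, 0.15, 0.65), other uniform — and are
**rejection-sampled until they satisfy their own category's rules**, so
the generating category is exact by construction and recovery
experiments measure measurement noise only. Margins of ~3 Dirichlet
standard deviations to the nearest rule boundary keep intrinsic boundary
flips rare.

Counts are negative binomial with size 200 (replicate CV ≈ 7%,
appropriate for replicates that each pool ~20 sectioned eggs) around
abundance × fraction × segment distortion, with log-normal abundances
(median 2000, log-sd 1.0 — deep coverage; the ~0.3% of genes below the
read-15 filter are removed, as in the emulated protocol). Anchor genes
(default panel of 10 spanning the categories, mirroring a 10-assay qPCR
tomography design) have archetype-exact fractions and Cq values
−log2(fraction) plus an offset, with 0.2 cycles of technical noise and a
per-replicate plate offset by default; a noise-free mode (exact
real-valued counts, exact Cq) supports exact size-factor recovery.
Protein intensities are log-normal with σ = 0.05 — enough that
borderline "even" proteins fall into *other*, as in the emulated data.

3′UTRs are iid sequences (uniform composition) with log-normal lengths
(median ≈ 900 nt); planted motifs (default TTCAC at Poisson rate 2 per
UTR in vegetal and extremely vegetal genes) overwrite non-overlapping
random positions, which are recorded in the ground truth. Homoeologue
pairs duplicate a fraction (default 0.30) of base genes into .L/.S; the
designed discordant subset is **round(q × n_pairs) pairs exactly**
(deterministic, so the designed concordance is the condition, not a
random variable); discordant .S copies are re-assigned to a different
category with a re-drawn profile; .S UTRs reuse the .L background mutated
at 5% per base, and motif planting follows each copy's own category, so
discordant vegetal/animal pairs acquire asymmetric zipcode content.

What the generator does *not* emulate: alignment/counting artifacts,
non-uniform base composition and repeat structure of real UTRs, length–
category correlations, mRNA secondary structure, and proteome missingness.
Passing recovery tests therefore validate the statistical machinery under
the stated model, not performance on real libraries.

## Problem sizes and numerical choices

Default validation sizes (2000 genes, 480 UTRs, 1000 pairs, 10,000 null
replicates, 100,000 simplex points) run the whole suite in about a
minute on one CPU; they are the package's chosen desk-scale versions of
the emulated study's 15,005 mRNAs and 3,500 pairs. Fractions are
validated to sum to 1 within 1e-6 on input and reproduce 1e-9 internally;
PWM rows must sum to 1 within 1e-6; the PWM score grid is 1e-3 bits
(configurable); UPGMA tie-breaks are lexicographic for determinism. All
randomness flows from a single integer seed through
`numpy.random.Generator`; identical config + seed reproduces every output
byte for byte.

## Known limitations

The k-mer test's anticonservatism (above) means raw significant-k-mer
counts should not be compared across k or between datasets with different
UTR length distributions. The IUPAC consensus of a PWM (bases with
probability ≥ 0.25 per column) is a lossy reduction used only for k-mer
cross-referencing. Concordance estimates from noisy counts are biased
slightly downward because either member's misclassification breaks a
pair. The CLI exposes each stage, but family-threshold selection for
motif clustering remains a judgment call for the user.
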