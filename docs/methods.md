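# Methods

This note documents the models and procedures implemented in `telncrna`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## The discovery cascade

A candidate is retained as a high-confidence lncRNA when all of the
following hold: length ≥ 200 nt; judged non-coding by *both* external
coding-potential predictors (a CPC2-style score below −1 **and** a
CNCI-style non-coding label — the intersection, not the union); no
protein-family (Pfam-style) hit with e-value ≤ 1e-5 (the boundary itself
rejects, the conservative reading); longest ORF < 100 amino acids; class
code `u` or `i` against the gene annotation; and FPKM strictly above 1 in
at least one sample. Filters are evaluated in a fixed order
(length → coding potential → protein family → ORF → class code → FPKM), but
every filter is always evaluated, so the order affects only the recorded
rejection reasons, never membership.

**ORF scanning.** An ORF is an ATG…in-frame-stop pair wholly inside the
transcript, scanned on the annotated strand in all three frames (transcripts
are stranded assembly products). Nested starts sharing a stop count once
(the longest per stop is kept); the reported length excludes the stop codon.
`orf_count` counts only ORFs of ≥ 30 aa by default — counting every
ATG–stop pair would make a "single-ORF" description meaningless for any
200-nt sequence — while the pass/fail rule uses only the longest ORF.

**Class codes.** `u` means the transcript span overlaps no annotated gene
span; `i` means every transcript base lies within the introns of a single
gene with no exon contact. A transcript that overlaps a gene span without
being fully intron-contained is `excluded` even if it touches no exon: such
fragments cannot be confidently called independent loci. When a known-lncRNA
annotation is supplied, `u`/`i` candidates inside or overlapping known
lncRNA loci are relabelled rather than dropped, which yields the
four-category accounting (intergenic / intronic / within known / overlapping
known) whose row sums must equal the totals — an invariant the tests check
on every run.

**polyA origin.** A transcript is polyA− when it exceeds the FPKM threshold
in at least one total-RNA library and in no polyA+ library. A transcript
expressed nowhere is polyA+ by convention and flagged; the FPKM filter
removes it regardless.

**Internal coding-potential stand-in.** When external predictor tables are
absent and strict mode is off, a transcript is called non-coding when its
longest ORF is < 100 aa *and* covers < 35 % of its length. This stand-in
exists so the pipeline runs end-to-end without external tools; it is not a
reimplementation of those predictors and is off (strict mode) by default.

## TE masking and enrichment

Sequence-similarity masking is represented by positional overlap between
transcript exons and the TE annotation; for the synthetic data the two
coincide by construction, and a precomputed RepeatMasker `.out` on real
lncRNA sequences can be ingested instead. Bases covered by several
superfamilies count once toward the masked total and are attributed to the
family with the larger local (per-transcript) overlap, ties going to the
lexicographically smaller name — so masked_fraction ≤ 1 always and the
per-family base counts partition the masked bases. Any positive overlap
calls a TE-lncRNA (configurable; the any-overlap default matches how such
catalogues report "overlapped with known TEs"). The enrichment table
compares each superfamily's share of TE-lncRNA bases against its share of
all genomic TE bases; both percentage columns sum to 100 and their ratio is
the enrichment fold, reported per superfamily and per grouped class
(retroelements, DNA transposons, helitrons, unclassified). χ² contrasts are
Pearson, df = 1, no continuity correction.

## Differential expression

Counts are normalized by median-of-ratios size factors (median over
transcripts with nonzero counts everywhere of count/geometric-mean, rescaled
to geometric mean 1; library-size ratios as fallback). The test is a
purpose-built NB Wald test, not a wrapper around an external DE package:
per-transcript dispersion α (variance μ + αμ²) by method of moments on
within-arm residuals pooled across the two arms (floor 1e-8); log2FC from
group means with pseudo-count 0.5; the standard error from the NB variance
by the delta method. The Wald statistic is referred to a **t distribution
with n_T + n_C − 2 degrees of freedom** rather than a normal: with 3
replicates per arm the plug-in dispersion is noisy and a normal reference
inflates the type-I error to ~0.11, while the t reference keeps it at
0.04–0.06 (and converges to the normal for large designs). No dispersion
shrinkage, no outlier filtering, no independent filtering — deliberate
simplifications; the contract is calibration and effect recovery on
simulation, not numerical agreement with any particular package. Adjustment
is Benjamini–Hochberg; Bonferroni is reserved for term enrichment. The DE
rule is |log2FC| > 1 (absolute value, so down-calls mirror up-calls) and
adjusted p < 0.05.

## Co-expression network

Expression is `log2(count/size_factor + 1)` — a variance-stabilizing
approximation adequate at these scales; zero-variance rows are excluded.
Adjacency is unsigned, `|pearson|^β` with β = 12. TOM follows the standard
unsigned formula given in the README. Modules come from average-linkage
clustering of 1 − TOM with a **flat cut at height 0.9** and minimum size 20;
clusters below size become `grey`. The cut height was derived from the
planted geometry rather than borrowed from eigengene-merging conventions: at
β = 12 a within-module correlation of 0.9 yields within-module TOM ≈ 0.3
(dissimilarity ≈ 0.7) while unrelated transcripts sit at dissimilarity
≈ 1.0, so any cut between ~0.75 and ~0.99 separates planted modules from
background; 0.9 is the midpoint. (A cut at the eigengene-merging value 0.25
can never form modules under this adjacency — no pair of imperfectly
correlated transcripts reaches TOM 0.75.) Labels `M1, M2, …` order modules
by decreasing size with ties broken by the smallest member id, making the
labelling invariant to input order.

Eigengenes are the first principal component of the row-standardized member
matrix, sign-fixed to correlate non-negatively with the members' mean
profile. Module–trait correlations use one-hot (condition × stage)
indicators, with p from t = r√((n−2)/(1−r²)); the same machinery yields
per-transcript gene significance. kME is the transcript–eigengene
correlation, kIM the within-module adjacency row sum. A hub must rank in
the top ⌈10 %⌉ of its module by kIM, have own-module kME > 0.9, and have
gene significance p < 0.01 against the module's best-correlated trait — the
gene–trait reading of "significance in the module", recorded per hub.

## Downstream statistics

Nearest genes are found by span-to-span gap distance (not TSS-to-TSS; the
choice is unstated in the catalogues this mirrors), ties preferring the
upstream gene and flagged. Cis correlation pools (lncRNA log2FC,
nearest-gene log2FC) pairs across contrasts and reports Pearson r with a
t-distribution p — correlation of *responses*, not of raw expression.
Entropy uses (condition × stage) group means, p_g = mean_g/Σ mean_g,
H = −Σ p_g log2 p_g; the grouping is configurable since expression-breadth
conventions differ. Term enrichment is the one-sided hypergeometric upper
tail (equivalently Fisher exact, greater) with Bonferroni over the tested
terms. ΔΔCt propagates the four cell variances into an SE on the fold scale
as fold·ln2·SE(ΔΔCt).

## The synthetic generator

One chromosome (default 2 Mb) is tiled with non-overlapping blocks — TE
elements, genes, and intergenic lncRNA loci — shuffled and separated by
gaps of at least 200 bp, with leftover space distributed multinomially.
TE element lengths are family-typical (LTR 4–12 kb, DNA 0.5–3 kb, SINE
150–400 bp, …) and drawn until each superfamily reaches its share of the TE
space (default 30 % of the genome; shares mirror a maize-like landscape:
Gypsy 0.596, Copia 0.324, DNA total 0.060). Genes carry 2–5 exons and a
planted ORF of ≥ 150 aa written into the genome, so every coding transcript
fails the lncRNA ORF rule by construction. lncRNA sequences are
rejection-sampled to have longest ORF < 100 aa (with an ATG-stripping
fallback that always terminates). TE-lncRNAs are carved out of TE elements
(occasionally overhanging one edge by ≤ 10 %, hence always ≥ 90 % masked);
families donate lncRNAs in proportion to their genomic share except DNA
superfamilies, which are over-sampled 2× by a bp-deficit scheme that holds
the realized composition on target even though short DNA elements truncate
slices. A configured fraction of the remaining lncRNAs sits wholly inside
introns.

Counts are negative binomial with variance μ + αμ² (α = 0.1, a typical
bulk-RNA-seq overdispersion). Per-transcript base expression is log-normal
around class means chosen to mirror the 3×/6× coding-vs-lncRNA/TE-lncRNA
expression gaps such catalogues report (12 / 4 / 2 FPKM), floored at a
detectability level because every planted transcript models an *assembled*
transcript, which only exists given expression evidence; total-RNA-only
lncRNAs get a higher, length-aware floor since they must clear the FPKM
filter in just two libraries, and their counts are zeroed in every polyA+
sample. Planted structure is layered in a fixed order with disjoint
supports so each truth is individually recoverable: (1) **modules** — a
per-module latent factor z, partially driven by one stress trait
(strength 0.7), enters the log-mean with a per-member loading calibrated so
each member's latent variance share equals the target within-module
correlation (0.9); the designated hubs are the module's most highly
expressed members, coupled at 0.98, which makes them its most connected
transcripts by construction; (2) **cis pairs** — intergenic, polyA+,
non-member lncRNAs paired with distinct non-member nearest genes, both
receiving per-contrast log2FC effects correlated at the target r = 0.5
(lncRNA base expression floored at 10 FPKM: cis pairs model DE-detected,
hence testable, lncRNAs); (3) **binary DE** — ±2 log2FC shifts on a random
subset of the remaining polyA-visible transcripts, with a configurable
shared fraction across contrasts. All randomness flows through one seeded
generator; identical configs produce byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level errors and mapping ambiguity, isoform
complexity and mis-assembly, batch effects, GC/length biases, genuine
sequence homology between TEs and lncRNAs (overlap is positional), the
empirical CPC2/CNCI/Pfam error processes (evidence tables are
truth-driven), and dispersion trends over the mean.

## Problem sizes and degenerate inputs

Default desk scale: 2 Mb genome, 200 genes, 150 lncRNAs, 36 polyA+ samples
({control, heat, cold} × {V3, V4, V6}, 4 replicates) + 2 total-RNA
libraries — the full pipeline runs in seconds, and the recovery benchmarks
(20 generator seeds, a 2000-transcript null, a 540-pair cis panel) in well
under a minute each. Degenerate inputs have defined behavior: empty
interval lists merge to empty and overlap 0; all-zero transcripts get
log2FC 0 and p 1 and entropy NaN; single-member modules return the member's
z-scored profile as eigengene; an empty hub set is valid; zero-margin χ²
tables, missing Ct cells, selections outside the enrichment universe, and
missing evidence under strict mode raise errors naming the offender.
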