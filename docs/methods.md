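# Methods

## Scope and data model

All computations operate on a `GenotypeDataset`: a samples × SNPs matrix of
unphased diploid genotype codes (0/1/2 = alt-allele count, −1 = missing)
with a SNP map (chromosome, region label, 1-based bp position) and a
population label per sample. Regions are 1-Mb windows on distinct
chromosomes, so intra-region SNP pairs are linked and inter-region pairs
are an empirical null for unlinked loci.

## Quality control

QC is per population, in a fixed order so that the report categories are
reproducible: call rate < 0.80 first, then monomorphism within the
population, then MAF below the cutoff (computed from called genotypes of
that population only). A SNP is tallied in the first category it fails;
the four categories always sum to the panel size. Two MAF cutoffs (0.05
and 0.1) are analysed because the cutoff choice systematically inflates
downstream LD-extent estimates: removing the 0.05–0.1 band removes pairs
whose low-MAF member caps r² from above.

## Two-locus haplotype frequencies and LD

For a pair of biallelic loci, every cell of the 3×3 joint genotype table
determines its two haplotypes except the double heterozygote, which is
either coupling (AB/ab) or repulsion (Ab/aB). The estimator is the
standard composite direct-counting + EM maximum-likelihood fit under
random mating:

* E-step: the coupling probability is f_AB·f_ab / (f_AB·f_ab + f_Ab·f_aB);
* M-step: haplotype counts = phase-known counts plus the split double
  heterozygotes, divided by 2n.

Starts: balanced (0.5) plus coupling- and repulsion-biased restarts
(0.9/0.1) with best-likelihood selection; convergence at max frequency
change < 1e-10, cap 10,000 iterations. Marginal allele frequencies are
invariant under the updates, so fitted marginals always equal sample
frequencies. For a table containing only double heterozygotes the
likelihood 2(f_AB·f_ab + f_Ab·f_aB) has two symmetric global maxima
(perfect coupling and perfect repulsion) and a saddle at the balanced
point; the restarts select a maximum deterministically and the result is
annotated "degenerate". The EM is vectorised across pairs (the state per
pair is four frequencies), which is what makes region-scale all-pairs
scans cheap; the per-pair algorithm is unchanged.

From fitted frequencies: D = f_AB − p_A·p_B, r² = D²/(p_A p_a p_B p_b),
|D′| = |D|/D_max with the usual sign-dependent D_max. r² ≤ |D′|² holds
identically and is asserted in tests. Pairs use pairwise-complete
individuals (not listwise deletion), and pairs whose usable subset turns a
locus monomorphic are dropped and counted. Background LD is the plain mean
of r² over all inter-chromosome pairs at MAF ≥ 0.1.

## Decay model

Expected r² at drift–recombination equilibrium for the population
recombination parameter C and n sampled diploid individuals:

    E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]

strictly decreasing in C from (5/11)(1+18/(11n)) at C = 0 to 1/n as
C → ∞. The fit sets C = a·d (d in kb) and minimises the unbinned sum of
squared residuals over all intra-chromosome pairs in a > 0 — no distance
binning, no weighting. Initialisation is a 121-point log-grid over
a ∈ [1e-6, 1] per kb followed by bounded scalar refinement (xatol 1e-12).
A fit pinned at the upper grid edge means r² sits at the 1/n floor with no
decay signal and is flagged non-converged; a fit at the lower edge is kept —
it simply means LD does not decay measurably over the observed range, and
the half-decay summary then reports its sentinel.

`n` in the model is the number of **individuals**, not chromosomes: with
that convention the analytic half-decay level ½(5/11)(1+18/(11n))
reproduces the per-population r² levels a real panel of this design prints
(0.27 at n=8 down to 0.25 at n=19); with n = 2×individuals it does not. A
flag allows the chromosome convention.

The half-decay point uses the C→0 limit as the curve maximum (not the value
at the smallest observed distance), making the level data-independent; the
crossing distance is solved by bisection to 1e-6 kb, and distances beyond
1000 kb report a `>1000` sentinel. Because C = a·d, d₅₀·a is a constant
that depends only on n; doubling a exactly halves d₅₀.

MAF inflation is 100·(d₅₀@0.1 − d₅₀@0.05)/d₅₀@0.1 — the denominator is the
MAF-0.1 estimate, which keeps the percentage below 100 by construction;
the statistic is undefined when either fit fails or either half-decay
point is unreached. GWAS-informative fractions count pairs with r² ≥ 0.8
per half-open distance class [lo, hi) kb over
{0–20, 20–40, 40–60, 60–80, 80–100, 100–200, 200–400, 400–600, 600–1000};
an empty class is reported missing, never zero.

## Haplotype blocks

A block [i..j] under the solid-spine rule requires |D′|(i,k) ≥ 0.8 for all
k in (i..j] and |D′|(k,j) ≥ 0.8 for all k in [i..j) — the two end markers
must each be in strong LD with every marker between them, while
intermediate-vs-intermediate pairs are unconstrained (the rule's prose is
ambiguous on that point; we require nothing of them). Blocks are found by
left-to-right greedy extension to the farthest valid end and never
overlap; a NaN (undefined) |D′| entry fails the condition. Markers enter
at MAF ≥ 0.05.

Within-block haplotype frequencies come from a multi-locus EM over phase
configurations: each individual's compatible ordered haplotype pairs are
enumerated (2 per heterozygous site, 4 per missing site; individuals with
more than 4096 configurations are excluded), and frequencies are updated
from posterior pair weights. Blocks longer than 8 markers are handled by
partition–ligation: solve each half recursively, keep the top 20
haplotypes per side, and re-run the EM over the ≤400 concatenations.
Haplotypes are reported down to frequency 0.01 and classified as the
single major haplotype, intermediate (> 0.1) or pooled rare, with the
pooled-rare mass defined as 1 − Σ(major+intermediate) so reported masses
always total 1.

## Population statistics

* Per SNP, Ho = fraction heterozygous among called; He = 2p(1−p)·2n_c/(2n_c−1)
  (small-sample corrected, n_c = called individuals). Ho and He are means
  over SNPs and F_is = 1 − Ho/He (monomorphic SNPs contribute zero to both
  means, leaving F_is unchanged).
* Tajima's D treats the 2n chromosomes of n diploids as sequences: π is
  the frequency-based unbiased pairwise diversity (phase-free), θ_W = S/a₁,
  and the variance uses the canonical constants. Per-site frequencies use
  called genotypes; the constants use the full sample size (an
  approximation under scattered missingness). S = 0 → undefined.
* F_st is a Hudson-type ratio-of-averages moment estimator:
  num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), den = p₁(1−p₂)+p₂(1−p₁),
  summed over SNPs before dividing, with nᵢ the called diploid
  individuals. This deliberately replaces model-based (admixture-style)
  differentiation estimates: the matrix feeds tree building, and absolute
  F_st values are not claimed comparable to model-based ones. The
  finite-sample correction divisor follows the diploid-count convention;
  with allele counts the correction would be roughly halved.
* Neighbor joining is the canonical Saitou–Nei agglomeration (Q-matrix
  minimisation, standard branch lengths), hand-implemented to guarantee a
  deterministic tie-break (sorted label pair on equal Q) and zero-clamping
  of negative branch lengths with a log note; on additive matrices it
  reproduces the generating tree's path-length matrix exactly (tested
  against graph-shortest-path oracles and cross-checked against
  scikit-bio's NJ).

## Synthetic panels

The generator emulates the study design end to end: ten 1-Mb regions on
distinct chromosomes, 150 SNPs per region with 50 packed into the first
100 kb; two ancestral pools (per-SNP frequencies Beta(0.5, 0.5) truncated
to [0.05, 0.95]; the second pool drifted by a step of variance F·p(1−p),
F = 0.05); pools evolved 150 forward Wright–Fisher generations (400
diploids) to accumulate standing LD; each population founded by a draw of
founders followed by a bottleneck and an expansion (qualitative
strong/moderate/weak severities); 2% missing calls. Recombination is
Poisson per gamete with mean 1e-8/bp × 1 Mb; regions assort independently.
There is no mutation during breed history — the panel is pre-ascertained.
Everything is a pure function of (config, seed), and phased truth
haplotypes (plus founder haplotypes) are emitted for oracle tests.

The `cat_panel` preset instantiates the study roster: 23 sampled
populations totalling 408 individuals with the study's per-population
sample sizes, pool memberships chosen so eastern-derived breeds share one
pool, and bottleneck severities assigned so long-LD breeds get few
founders. The combined random-bred population is a pooled view of the two
random-bred samples, not extra individuals. The severity parameters were
pitched so the share of SNPs surviving QC lands in the range a real panel
of this design reports; at this scale the simulated mean retention (~51%)
still sits below the real ~66%, because desk-scale pool sizes drift more
than a real species-wide population.

What passing tests on these panels do and do not show: directional and
structural behaviour (tighter bottleneck ⇒ longer d₅₀, fewer/longer
blocks; pool split ⇒ east/west tree bipartition; background LD ~0.05–0.09)
transfers to real panels; absolute d₅₀ values do not — forward simulation
at hundreds of diploids cannot reach the short-range recombination
equilibrium of a large random-bred population, so simulated d₅₀ are
compressed upward (weak-bottleneck populations land at hundreds of kb
rather than tens). A known, deliberate gap: with a pre-ascertained,
common-biased panel and no mutational input, Tajima's D after a
bottleneck-plus-expansion history is positive (rare-variant input is what
drives the classic negative-D expansion signature); the statistic itself
is verified against hand-computed values, and the bottleneck's upward push
on D is tested instead.

## Numerical choices and problem sizes

Tolerances: EM 1e-10 (frequencies), decay refinement 1e-12 (a), bisection
1e-6 kb, block EM 1e-9. Test suites run the simulator at reduced scale —
2–3 regions of 40–60 SNPs, 8–10 seeds for directional medians — which
keeps the full suite within a few minutes while preserving the contrasts
being tested; the analysis drivers run the full 10-region, 408-cat preset.

## Known limitations

* Diploid-only; X is treated as diploid for all individuals (an optional
  sex column can exclude male X calls, off by default).
* Tajima's D constants assume complete data; scattered missingness is
  absorbed into per-site frequencies only.
* The F_st estimator's correction convention (diploid counts) makes
  absolute values slightly conservative relative to the allele-count
  convention.
* The simulator omits mutation, migration and selection; its presets are
  qualitative, and any quantity tied to the rare end of the frequency
  spectrum is outside what it can reproduce.
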