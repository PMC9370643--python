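# Methods

## The contrast and its statistic

The pipeline contrasts transcript-level read counts between two groups of
sequencing libraries (typically the high-BNF and low-BNF sugarcane
genotypes within one tissue × growth-condition cell of the 16-library
factorial). For a transcript with pooled counts $c_A, c_B$ and pooled
library sizes $T_A, T_B$:

- **RPKM**: $\mathrm{RPKM} = c \cdot 10^9 / (T \cdot L)$ with $L$ the
  transcript length in bp. When $T$ equals the column sum of counts,
  $\sum_t \mathrm{RPKM}_t L_t = 10^9$ exactly.
- **Fisher exact test**: the 2×2 table
  $[[c_A, T_A - c_A], [c_B, T_B - c_B]]$ is tested two-sidedly.
  Conditioning on the margins, the first cell is hypergeometric; the
  two-sided p sums the probabilities of all tables whose probability is at
  most that of the observed table, with a relative slack of $10^{-7}$ on
  the comparison to absorb floating-point ties. The support has at most
  $c_A + c_B + 1$ points, so exact evaluation is cheap even at
  library-scale totals; log-weights are computed with `scipy.special.gammaln`
  and renormalized per table.
- **Bonferroni**: adjusted $p = \min(1, p \cdot m)$ with $m$ the number of
  transcripts actually tested in the comparison (nonzero pooled count in
  at least one group). A global-$m$ override exists for across-comparison
  control. Calls require adjusted $p < \alpha$ (default 0.05) and follow
  the direction of the larger RPKM; an optional $|\log_2 FC|$ floor
  (default 0) can be added.
- **Fold change**: $\log_2((\mathrm{RPKM}_A + \varepsilon)/(\mathrm{RPKM}_B
  + \varepsilon))$ with reporting pseudocount $\varepsilon = 0.25$ RPKM.
  The pseudocount affects reporting only — calls rest on the p-value and
  RPKM direction — and transcripts with all-zero counts on one side are
  additionally routed to the exclusivity rule.
- **Exclusivity rule**: a transcript is exclusive to a genotype iff it has
  ≥ 1 read in at least 5 libraries (configurable) of that genotype and
  zero reads in every library of the other. This is reported
  independently of the DET calls, with the overlap flagged, because a
  fold change against zero is not meaningful.

Two replicate-handling modes exist. POOLED (default) sums counts within
each group and yields one p per transcript per comparison; it matches the
two-replicate design and RPKM-ratio reporting. PER_PAIR_CONSENSUS tests
every (library-in-A, library-in-B) pair and calls a transcript only when
all pairs are significant in the same direction, taking the largest pair p
as the reported p — a stricter emulation of library-by-library testing.

## Set algebra and enrichment

DET sets from several comparisons are partitioned into Venn regions by
membership signature (directions ignored by default, since region counts
are transcript counts; a directional mode splits opposite-direction calls).
The "common pattern" intersection keeps transcripts called in both a
naturally colonized and a bacteria-free comparison with the same genotype
direction; root and shoot intersections are disjoint, so their reported
total is the plain sum. Summary percentages use half-up decimal rounding.

Enrichment of a DET foreground (size $n$) against an annotated background
(size $N$) uses the upper-tail hypergeometric $P(X \ge k)$ for each term
with $K$ background members, computed with `scipy.stats.hypergeom.sf`. The
Rich Factor is $k/K$, the per-category foreground fraction, following the
per-category reading of that statistic. The default background is the set
of annotated transcripts present in the count matrix; the default
significance rule is raw $p < 0.05$, with Benjamini–Hochberg available but
off by default.

## Validation quantifications

**qPCR (ΔCt)**: relative expression is $E^{-\Delta C_t}$ with
$\Delta C_t = C_t^{target} - \tfrac12(C_t^{ref1} + C_t^{ref2})$ and
amplification factor $E$ (default 2). Averaging the two reference Cts
(28S rRNA and GAPDH) equals normalizing by the geometric mean of the
reference quantities. Two-sample ratios are means of replicate quantities
with first-order error propagation
$\sigma_r = r\sqrt{(\sigma_A/\mu_A)^2 + (\sigma_B/\mu_B)^2}$, and sign
concordance against RNA-seq log₂ fold changes treats zero as matching
nothing.

**MPN**: each tube at ladder exponent $e_i$ receives
$v_i = 0.1 \cdot 10^{e_i}$ mL of undiluted homogenate (100 µL inoculum,
ten-fold steps $10^{-1}..10^{-9}$). Under the single-hit Poisson model a
tube is positive with probability $1 - e^{-c v_i}$, giving the likelihood
$\prod_i \binom{n_i}{p_i}(1 - e^{-c v_i})^{p_i} e^{-c v_i (n_i - p_i)}$.
The score function is strictly decreasing in $c$, so the MLE is found by
bisection at geometric midpoints over $[10^{-6}, 10^{15}]$ organisms/mL to
$10^{-9}$ relative tolerance. All-negative ladders return 0
(ALL_NEGATIVE); all-positive ladders return the bracket limit flagged
ALL_POSITIVE (a lower bound). The optional interval estimate is
$\log_{10}\hat c \pm 1.96\sigma$ with $\sigma$ from the observed
information for $\ln c$. CFU·g⁻¹ multiplies by the homogenate factor,
default 10 mL/g (1 g in 9 mL saline, volumes additive; overridable, e.g.
9.9 for density-corrected homogenates). Tubes per dilution default to 3 in
simulations (1 is accepted, matching single-tube ladders).

## Synthetic data

`simulate_experiment` emulates the study design: 16 libraries (2 genotypes
× 2 tissues × 2 growth conditions × 2 replicates), counts drawn
negative-binomially with variance $\mu + \phi\mu^2$ ($\phi = 0.1$ default,
the common RNA-seq overdispersion scale; $\phi = 0$ gives Poisson).
Defaults: 500 transcripts, $10^6$ reads per library, per-library baseline
means $2^{N(5, 1.5)}$ (median 32 reads), lengths uniform on [200, 5000] bp,
10% DE at $|\log_2 FC| = 2$ split symmetrically between genotypes (each
genotype shifted $2^{\pm \log_2 FC/2}$, so the planted contrast is exact),
2% exclusive transcripts forced to zero in one genotype and to ≥ 5
positive libraries in the other. One master seed spawns independent
substreams (`numpy.random.SeedSequence`) for lengths, baselines, counts,
assignment and exclusivity placement, so every generator is a pure
function of (config, seed).

What the generator does *not* emulate: read-level effects (mapping bias,
multi-mapping across the polyploid transcriptome's isoforms), GC/length
bias, correlated replicates, library-composition effects, and annotation
structure beyond independent term assignment. Passing recovery tests
therefore demonstrate correctness of the statistics under the stated
sampling model, not robustness to those real-data artifacts.

`simulate_annotation` plants one term whose odds among DE transcripts are
multiplied by a chosen factor (base term probability 0.1);
`simulate_dilution_series` draws tube outcomes from the same single-hit
model the estimator assumes; `simulate_ct_table` offsets target Cts by
$-\log_2(\text{ratio})$ with Gaussian Ct noise.

## Numerical and design choices

- The Fisher tie comparison uses relative slack $10^{-7}$; the tail logic
  is evaluated in renormalized weight space, so the constant
  $\binom{N}{k}$ cancels. Tables are processed in width-sorted chunks to
  keep the padded support near each chunk's own size.
- N50 is the length at which the descending cumulative sum first reaches
  half the total (the dominant convention); ties in BLAST best-hit
  filtering break by larger bit score, then input order.
- Library totals default to column sums (self-contained and reproducible);
  a side file can supply sequenced-read totals, which may exceed mapped
  column sums.
- Enum vocabularies are case-insensitive on input; FASTA ids truncate at
  the first whitespace; count-matrix ids must match exactly.
- Percent rounding is half-up (`decimal` module), not banker's rounding.

## Known limitations

- **The pooled Fisher test is anticonservative under overdispersion.**
  The test models sampling as binomial at fixed proportions; biological
  replicate variability (NB $\phi > 0$) inflates the variance of pooled
  counts by roughly $1 + \phi\mu$ per library. The package's own null
  simulations quantify this: at $\phi = 0.1$ and the default expression
  scale, essentially every 500-transcript null run yields Bonferroni
  false calls, whereas at $\phi = 0$ the family-wise error rate sits at
  its nominal 5% (see `tests/test_acceptance.py` and the
  `null_fwer_*` entries written by `scripts/acceptance.py`). Large DET
  fractions produced by this class of method should be read accordingly;
  dispersion-modelling DE methods are out of scope here by design.
- PER_PAIR_CONSENSUS reports the worst pair p, which is conservative and
  not a calibrated combined p-value.
- The MPN interval estimate is a large-sample approximation; for 3-tube
  ladders it is indicative only.
- Enrichment treats terms independently (no GO DAG propagation or
  pathway topology) and assumes the background is exchangeable with the
  foreground draw.

## Problem sizes

Default test and acceptance runs use 300–2000 transcripts, 16 libraries at
$10^6$ reads, 1000 (NB) and 400 (Poisson) null replicates, 200 enrichment
replicates and 500 dilution-series replicates — sizes at which every
statistic above is estimated stably while the whole suite completes in a
few minutes on one core.
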