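# Methods

`tfselect` quantifies natural selection on the two motif classes of
transcription-factor (TF) biology — DNA-binding domains inside TF coding
sequences (TF-BDs) and noncoding binding sites (TF-BSs) predicted inside
cis-regulatory modules (CRMs) — from population variant data with an outgroup.
This note records the models, the defaults and why they were chosen, what the
synthetic data do and do not emulate, and the numerical decisions that shape
the results.

## Region classes

Five classes partition the analysis: `BD` (binding-domain coding intervals),
`NONBD` (the set-complement of BD within each TF's coding span), `ALLGENES`
(the full coding space, TFs included), `CRM` (scored regulatory modules), and
`TFBS` (motif hits inside retained CRMs). CRMs are retained when their
annotation score strictly exceeds 30 — the score counts distinct regulators
bound there, so >30 marks heavily bound hotspots — and when they overlap the
union of gene-body ±2 kb windows by at least 500 bp (250 bp is the documented
setting for compact genomes). The gene body is included in the vicinity
window; this is the permissive reading, consistent with the observation that
nearly all retained modules sit next to genes anyway. Overlapping CRMs are
filtered independently, never merged, because they are database records, not
genomic segments. A variant inside several overlapping TFBS intervals counts
once: binding sites are dense inside CRMs, and pooling avoids double-counting
a site that disrupts one motif while being neutral for another.

## Variant classification and polarization

Coding variants are classified synonymous/nonsynonymous against the reference
transcript codon under the standard nuclear code (configurable table).
Multiple hits in one codon are classified independently — the standard
approximation; at the diversity levels simulated here double-hit codons are
rare. Expected site counts follow Nei and Gojobori: each codon position
contributes (number of synonymous one-base changes)/3 to the synonymous
length, stop-gaining changes count as nonsynonymous, and L_syn + L_nonsyn
always equals the coding length. Polarization assigns the ancestral state from
a single pre-aligned outgroup base: sites where the outgroup matches neither
allele, or carries a gap/ambiguity, are rejected and tallied, never guessed.
Single-outgroup polarization mis-assigns some sites whose lineage carries a
substitution; these surface as spurious high-frequency derived variants, which
is why the analysis caps usable frequencies at 0.9 (below).

## Constraint ratios

The constraint ratio is the density of test-class variants over their expected
site length divided by the density of neutral-class variants over theirs:
pi_n/pi_s within populations, Kn/Ks against the outgroup. The default
estimator uses variant-count proportions — the procedure as stated, even
though the symbols suggest pairwise diversity; a classical
heterozygosity-weighted mode (`pi_mode="pairwise"`) is available. For TF-BSs,
which have no reading frame, every base is a potential functional change, so
the test site length is the total TF-BS bp and the neutral class is the
All-genes synonymous one.

Confidence intervals come from 500 nonparametric bootstrap cycles with the
locus as the resampling unit — genes for coding classes, CRMs for the TFBS
class — preserving within-locus correlation. Percentile (2.5/97.5) intervals
are reported. Class comparisons use Welch's unequal-variance t-test on the
bootstrap replicate distributions, mirroring the published procedure; these
p-values understate uncertainty (replicates are not independent observations)
and the output metadata says so.

## MK alpha: asymptotic fit, cutoffs, pooled test

Per frequency class x, alpha(x) = 1 − (Ds/Dn)·(pn(x)/ps(x)); classes with
ps = 0 are flagged missing, never imputed. The spectrum uses 50 equal-width
bins by default (the desk-scale experiments here use 20, matched to their
variant counts). The asymptote is a nonlinear least-squares fit of
a + b·exp(−c·x) read at x = 1, with a linear fallback (flagged) when the
exponential fails or c ≤ 0.

The low-frequency cutoff automates the visual "where does the curve stabilize"
judgment: f_low is the first class midpoint at which the fitted curve is
within delta (default 0.1) of its limit, relative to the fitted-curve range.
Two guards keep the rule faithful to what a human reader would do. First, the
automated rule only engages when the exponential fit improves on a flat curve
beyond sampling noise (chi-square improvement over the constant model, two
extra degrees of freedom, 5% level) — otherwise the curve is declared
converged at the first class, as any visual inspection of a flat curve would.
Second, fitted wiggles smaller than 0.05 alpha units are never chased
(`delta_abs`). With `delta_abs=0` the rule reduces exactly to the closed form
x = ln(|b|/(delta·range))/c. The high cutoff is fixed at 0.9 unless
overridden, discarding the classes contaminated by single-outgroup
mis-polarization.

The pooled traditional MK alpha, 1 − (Ds·Pn)/(Dn·Ps), uses polymorphisms with
f_low ≤ f ≤ f_high. Its CI resamples the retained polymorphism data (500
cycles). The polymorphism-only resampling understates uncertainty whenever
divergence counts are themselves noisy; the pipeline therefore also resamples
Dn and Ds as Poisson draws by default (`resample_divergence=True` in
`pooled_mk_alpha`), which restores ~95% coverage on synthetic data. The
polymorphism-only variant remains the function's default for procedural
fidelity.

Pathogenic-variant enrichment between BD and non-BD classes is a two-sided
Fisher's exact test on the 2x2 pathogenic/benign table, with the class
proportion defined as pathogenic/(pathogenic+benign). No multiple-testing
correction is applied anywhere; raw p-values are compared to the 0.01 bar.

## Synthetic data

The generator emulates a single-population resequencing study: one contig of
codon-structured genes (all on the + strand; strand handling is exercised by
the classification tests), a TF subset carrying a centered, codon-aligned BD
interval, noncoding flanks hosting scored CRMs with planted PWM consensus
motifs, an outgroup contig, haplotype genotypes, and synthetic benign /
pathogenic labels. Internal coordinates are 0-based half-open everywhere;
conversion to 1-based happens only when writing VCF/GFF3.

Polymorphism is drawn from the stationary diffusion site-frequency spectrum:
for scaled coefficient gamma = 2Ns the density of derived alleles at frequency
q is proportional to H(gamma, q) = (1 − e^{−gamma(1−q)}) / ((1 − e^{−gamma})
q(1−q)), the neutral 1/q in the limit. Expected class counts are theta · L ·
∫H·Binom(n,k,q) dq by quadrature, drawn as Poisson, with positions sampled in
proportion to each site's synonymous/nonsynonymous mutational opportunity so
that count-based pi_n/pi_s is exactly 1 under neutrality. Outgroup divergence
is Bernoulli per site at rate d for neutral classes, thinned at constrained
classes by the relative fixation probability u(gamma) = gamma/(1 − e^{−gamma}).

The nonsynonymous mutation mix defaults to 60% neutral, 39.5% deleterious at
2Ns = −9 (the purifying strength of the simulation experiment), and 0.5%
strongly beneficial at 2Ns = +100. The beneficial class is deliberately rare
and strong: the MK framework presumes adaptive mutations sweep quickly,
contributing divergence but negligible polymorphism. A moderately beneficial
class (say 2Ns = +10) segregates visibly at intermediate frequencies and
cancels part of its own divergence signal in alpha — a real phenomenon, but
one that would make "the injected adaptive fraction" ill-defined as a
recovery target. `FixtureConfig.expected_alpha()` gives the adaptive share of
expected nonsynonymous divergence implied by the mix; with the defaults it is
0.454. TFBS sites receive the same selective mixture (they are the
nonsynonymous equivalent); remaining noncoding sites are neutral.
Pathogenicity labels are Bernoulli draws on nonsynonymous TF-gene variants
with an odds multiplier inside BD; no clinical semantics are claimed.

What the generator does not emulate: linkage (sites are independent draws from
the stationary spectrum; the forward simulator is the linkage model),
demography, mutation-rate heterogeneity, indels, multiallelic sites, CpG
effects, and real-genome base composition. Tests passing on these fixtures
certify the statistical machinery — classification, normalization,
polarization, bootstrap calibration, cutoff logic — not robustness to those
real-data complications. Mis-polarization, however, is emulated naturally:
outgroup substitutions land on polymorphic sites at the realistic rate, so the
high-frequency artifact and the 0.9 cap are genuinely exercised.

## Forward simulation

The Wright–Fisher simulator models a diploid population with partial
self-fertilization: each offspring selfs with probability s, otherwise draws
two distinct parents, all proportional to multiplicative fitness with
semidominance (h = 0.5; the original simulation tool's default is not
restated anywhere, so this is a declared choice). Nonsynonymous sites carry
s = 2Ns/(2N) against the derived allele; synonymous sites are neutral;
classification uses a memoized codon lookup against the random stop-free
reference. Gametes recombine at per-bp rate r; mutations arrive as
Poisson(mu·2N·L) at uniform positions (duplicate positions are dropped — an
infinite-sites approximation costing <2% of the rate). After a burn-in of 10N
generations the population is cloned into ingroup and outgroup, which evolve
independently; divergence counts mutations fixed on exactly one branch,
excluding sites still polymorphic in the ingroup, so shared ancestral
polymorphism fixing on both branches cancels.

Selfing is modeled as a recent trait of the focal lineage: the burn-in
(shared ancestry) and the outgroup branch mate at `ancestral_selfing_s`
(default 0 — an outcrossing outgroup, as in the thale-cress/lyrata pair the
experiment mirrors), while the ingroup branch mates at `selfing_s`. Applying
high selfing to both branches instead lets Muller's-ratchet fixations drive
the divergence composition toward the mutational input, flattening every
alpha curve to zero; with the ancestral design the divergence stays
constraint-dominated and the ingroup spectrum carries the selfing signature.
Equilibrium oracles (diversity = 4Nmu/(1+F), F = s/(2−s)) set both rates
equal. Site-frequency spectra are sampled as one haplotype from each of
sample_n distinct individuals — the natural design for predominantly selfing
populations — and, in addition to the end-point sample, a time-averaged
spectrum accumulates a snapshot every N generations after the split.
Snapshots are partially correlated (the coalescent time scale is a few N),
but pooling them shrinks per-class noise severalfold, which the regime-level
curves need.

Rescaling follows standard diffusion practice: reduce N while holding 2Ns,
4N·mu, 4N·rec constant. The per-site scale here is N = 50, mu = 2e-5,
rec = 4e-5 (factor 4000 from the study's 2e5), preserving per-site diversity
and map length. Interference between linked selected sites, however, scales
with the genomic deleterious input theta·L, not with per-site rates — the
region length sets the Hill–Robertson regime independently, and no desk-scale
choice preserves both. Two scales therefore appear. The regime study uses
L ≈ 100 kb (theta·L ≈ 400): interference strong enough for selfing (which
multiplies effective recombination by 1−F) to move deleterious variants
visibly up the spectrum, while purifying selection still holds Kn/Ks near 0.3
in the outcrossing regime. The purifying-asymptote experiment uses
L ≈ 500 kb (theta·L ≈ 2000, closest to the full-scale setting's ≈ 4000),
where the full-range exponential fit recovers the zero asymptote. Post-split
branches run 1,000 (regime study) or 300 (asymptote experiment) generations,
enough for hundreds of synonymous fixations per branch.

The regime experiment runs selfing rates 0, 0.3, 0.6, 0.97 with ten
replicate seeds each, pools the time-averaged spectra and divergence counts
per regime (ten ~100 kb replicates stand in for one 1 Mbp region), and
reports each regime's alpha curve, fitted asymptote, convergence frequency
(first class of the fitted curve within delta = 0.1 of its plateau, with a
delete-one jackknife over replicates), and the nonsynonymous
frequency-elevation ratio — the mean derived frequency of nonsynonymous
variants relative to synonymous ones.

Two readouts of the selfing effect must be distinguished at this scale. The
frequency-elevation ratio is the direct footprint of selective interference
and rises strictly and reproducibly with the selfing rate (≈ 0.58 → 0.63 →
0.68 → 0.78 across the four regimes in every seed set tested): mildly
deleterious variants persist to higher frequencies as effective
recombination drops. The convergence frequency of the alpha curve, by
contrast, is dominated at reduced scale by how deep the curve's plateau sits:
under near-complete selfing the effective scaled selection collapses
(Ne shrinks by 1+F while interference grows), the curve becomes uniformly
deep-but-flat, and its own-plateau convergence point moves early rather than
late. The package reports both; only the ordering of the frequency-elevation
readout is scale-robust, and the known-limitations section below records the
convergence-ordering caveat.

## Problem sizes of the acceptance experiments

- Neutral-limit calibration: 50 fixtures of 100 genes x 200 codons,
  20 haplotypes, theta = 0.005; CI coverage of pi_n/pi_s = 1 and alpha = 0.
- Alpha recovery: 20 fixtures of 60 genes x 200 codons, 45 haplotypes,
  theta = 0.01, divergence 0.05; target is `expected_alpha()` = 0.454.
- Selfing regimes: N = 50, L = 99,999 bp, mu = 2e-5, rec = 4e-5, 2Ns = 9,
  burn-in 500, split branches 1,000 generations, sample 20, 10 replicates
  per regime.
- Purifying asymptote: as above but L = 499,998 bp, split branches 300
  generations, outcrossing only, 10 replicates, full-spectrum fit.

## Known limitations

- The count-proportion pi estimator tracks the stated procedure, not classical
  pi; the pairwise mode exists for comparison.
- Percentile bootstrap CIs on ratio statistics undercover slightly below ~50
  resampling units; the neutral-limit experiment quantifies this.
- The automated cutoff rule is a surrogate for visual inspection; it is
  overridable (`--f-low`) and its two guards are documented above.
- The forward simulator's rescaling preserves per-site compound parameters
  exactly but compresses the interference hierarchy (U/s is preserved only
  through the choice of L). Absolute convergence frequencies from the regime
  study are scale-bound, and even their ordering across selfing regimes is
  not reliable at this scale (the plateau-depth effect above); the
  frequency-elevation ratio is the scale-robust readout of the selfing
  effect.
- Welch tests on bootstrap replicates inherit the published procedure's
  anti-conservatism.
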