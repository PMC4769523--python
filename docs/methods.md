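# Methods

## The problem

At very high sequencing coverage (>1000×) a minor allele present in 0.1–1 %
of reads — mitochondrial heteroplasmy, a low-frequency somatic mutation, a
minor strain in a pool — is covered by enough reads to be detectable in
principle, but its read count is comparable to the count of bases that
simply miscall. Distinguishing the two rests entirely on the base quality
scores: a phred score Q asserts a per-base error probability
ε = 10^(−Q/10), and any systematic misstatement of ε propagates directly
into likelihood-based calling. This package recalibrates base qualities
against a spiked-in control sequence of known identity (e.g. phiX174) and
then calls minor alleles per site with a likelihood-ratio statistic.

## Recalibration model (SEGREG)

Every aligned, non-clipped base of the control library is assigned to a
**group** — the tuple (mate index, machine cycle, observed nucleotide,
previous-cycle nucleotide) — because these are the machine conditions that
error rates are known to depend on. For paired-end reads of length R this
yields 2·R·4·4 groups with a four-valued context (3200 at R = 100), plus
the cycle-1 groups whose context is the START sentinel, which are trained
identically but counted separately. Bases and context are taken in
sequencing (machine) orientation: for reverse-strand alignments the stored
sequence is complemented and the cycle runs from its right end, since
machine cycle and chemistry context are sequencer properties, not reference
properties.

Within a group, bases are binned by raw score x_i; with w_i bases and k_i
of them mismatching the control consensus (known control variants
excluded), the empirical quality of the bin is

    xe_i = −10·log10((k_i + 0.5) / (w_i + 0.5)),

clamped at 0. The +0.5 continuity pseudocount keeps zero-error bins finite
and usable; the bias it introduces is ≪0.1 phred for the bin sizes the
masking rule admits. Bins with w_i < 100 (configurable `min_bin_count`)
are masked as too noisy.

Each group is then fitted with a two-segment weighted least-squares
regression: find a0, b0, a1, b1 and a breakpoint bk minimising

    Σ_{x_i < bk} w_i (xe_i − a0 x_i − b0)² + Σ_{x_i ≥ bk} w_i (xe_i − a1 x_i − b1)².

The search over bk is exhaustive over midpoints between consecutive
distinct raw scores with at least two unmasked bins on each side; per
candidate the two line fits are closed-form, so the optimum is exact, not
heuristic. The two segments are deliberately **not** constrained to meet at
bk — the objective has five free parameters, and continuity would remove
one. Ties in SSE are broken toward the smaller breakpoint for determinism
(note that data lying exactly on two lines through a common vertex admit
several zero-SSE splits; the rule then picks the leftmost). Groups with
fewer than four unmasked bins (two per segment) get a FALLBACK fit that
passes raw scores through unchanged and increments a counter.

Applying the model maps each base of the user's data to its group (from
the read's own sequence — no alignment needed at application time),
evaluates the group's line at the raw score, rounds to the nearest integer
and clamps to [2, 60] so the result stays phred+33-encodable. Bases at
cycles never seen in training, N bases and N contexts keep their raw
scores (warned once). A quadratic-regression variant was considered and
not implemented: with realistic bin occupancy the extra curvature fits bin
noise, and the linear-per-segment form already captures the empirically
observed shape. The trained model serialises to a tab-separated text table
(one row per group, `#key=value` headers with training provenance) and
round-trips losslessly.

The simplest miscalibration this corrects is an additive background: if
the basecaller underestimates a systematic error rate b, a base emitted at
quality q truly errs at 10^(−q/10) + b, i.e. its true quality is
−10·log10(10^(−q/10) + b). For b = 10⁻³ this maps Q40 → 29.59 and
Q10 → 9.96 — large corrections at the top of the scale, negligible at the
bottom, which is why miscalibration matters most exactly where callers
place their trust.

## Minor-allele likelihood and filters

Per pileup site, the candidate minor allele is the non-major allele with
the most reads; third-allele residue is flagged but not modelled. With l
minor-allele reads (error rates ε_j) and k major-allele reads, the
likelihood of a minor-allele frequency f is

    L(f) = Π_{j=1..l} [(1−f) ε_j + f (1−ε_j)] · Π_{j=1..k} [(1−f)(1−ε_j) + f ε_j],

evaluated in log space (per-site likelihoods underflow doubles at depth
>2000). f̂ is the maximiser over f ∈ [0, 0.5] ("minor" by definition),
found by a 512-point grid followed by golden-section refinement to 10⁻⁶;
equal integer phred scores are collapsed to (ε, count) pairs first, which
makes the evaluation exact and fast. The evidence statistic is

    LLR = log10 L(f̂) / L(0),

floored at 0; base-10 logs are used so the conventional cutoffs (3, 5)
from the heteroplasmy literature apply, and the base is recorded in output
headers. Note the model charges a minor-allele observation to a major read
at rate ε_j, not ε_j/3: it does not condition on which wrong base an error
produces. Under a uniform error spectrum this overstates the null by up to
3×, making the LLR conservative — a deliberate property shared with the
established heteroplasmy pipelines this caller follows.

The filter battery, with defaults for high-coverage mtDNA work:

| filter | default | rationale |
|---|---|---|
| counting threshold | phred ≥ 20 | bases below Q20 carry little evidence and concentrate artefacts |
| strand support | ≥ 2 minor reads per strand | single-strand signals are dominated by strand-specific chemistry errors |
| ML MAF | f̂ ≥ 0.001 | below 0.1 % the realized minor-read counts are indistinguishable from error at practical depths |
| LLR | > 3 | 1000:1 likelihood ratio vs pure error |
| strand bias | SB < 1 | SB = −log10(p)/2 of a two-sided Fisher exact test on the minor/major × strand table, so SB < 1 ⇔ p > 0.01 exactly |
| read position | PosRankSum > −3 | tie-corrected normal z of the Mann–Whitney U on within-read positions, signed negative when minor bases cluster at late cycles where errors concentrate; −3 ≈ p 0.003 one-sided |
| masked regions | 302–316, 513–526, 566–573, 16181–16194 | rCRS repetitive/indel-prone segments; configurable |

Every scored site is reported with all flags; the passing subset is
marked. Indeterminate statistics (an empty stratum in the rank-sum test)
pass with a flag rather than silently dropping the site. The Ti/Tv ratio
of a call set is reported as an external error indicator: mtDNA variation
is strongly transition-biased (ratios ≫ 1) while uniform error gives 0.5.

## Simulator

The generator emulates very-high-coverage resequencing of a small circular
genome. Fragments start uniformly on the genome and extend into an
appended copy of the first `extension` (default 1000) bases, so circular
coverage is uniform; pileup construction folds extension positions back,
and a relocation operation implements the same convention for alignment
files (pairs fully inside the artificial repeat are shifted back; junction
reads stay in extended coordinates).

Per base, a **nominal quality level** is drawn from a discrete bimodal
distribution (defaults 2–40, most mass at 37/40, late cycles downgraded
with linearly increasing probability), and the **true** error rate is

    ε_true = 10^(−q_nom/10) + ctx(prev, base) · (background + ramp · cycle/R),

with deterministic context factors spanning the ~2.5-fold spread typical
of substitution-error tables. Substituted bases follow a uniform spectrum
by default (each alternative at ε/3 — the arithmetic behind
expected-error-read calculations) or a configurable 4×4 matrix. The
**emitted** score is an affine map of the nominal score, optionally with a
fraction of confidently read bases forced to the floor score 2
(basecaller pessimism). Truth is recorded per base; realized mixture
counts are recorded per planted site. All randomness comes from one
`default_rng(seed)` stream drawn in a fixed order (fragment starts,
lengths, levels, downgrades, pessimism, errors, substitutions), so output
is byte-identical per seed.

Default parameters: background 10⁻³ and ramp 10⁻³ (so the Q40 → 29.59
arithmetic above is the exact correction at the first cycle), matching the
background-underestimation model the recalibrator targets. Three presets
cover other study designs: `calibrated()` (no systematic component —
recalibration should be a no-op), `uniform(rate)` (one true error rate
everywhere, for closed-form checks), and `legacy_basecaller()`
(first-generation emission: 15 % pessimistic floor-score emission on
accurate bases, a small 10⁻⁴ underestimated background, and strong
G-context/A-read-as-C error hotspots invisible in emitted scores).

Two-template mixtures thin the minor library per fragment (both mates kept
together) with inclusion probability equal to the planted fraction, so
realized per-site minor counts are binomial around it; the truth set
records realized counts and MAFs, which — not the planted constant — are
the calling target. Truth sites come from global pairwise alignment of the
templates (edlib, unit costs; exact at the sub-percent divergences the
template generator produces), with SNPs within 5 bp of an indel excluded
as misalignment-prone. Mixtures require equal-length (substitution-only)
template pairs so minor reads map ungapped onto major-template
coordinates; coordinate liftover across indels is out of scope.

What the generator does **not** model: PCR and GC-composition bias,
optical duplicates, sequencing indels, adapter read-through, mapping
errors, correlated errors within a cluster, and overlap between mates
(mates are treated as independent observations). Results on simulated data
therefore show that the estimator recovers planted structure under the
stated error model, not that real libraries satisfy that model.

## Evaluation

Calibration accuracy is summarised by the frequency-weighted squared error
over predicted-score rows,

    FWSE = Σ_rows freq_row · (predicted − empirical)²,

computed over rows with ≥ 100 bases (the same masking philosophy as
training; configurable) with frequencies renormalised over the included
rows. FWSE is invariant to uniform count scaling. Detection performance is
summarised by the ROC over LLR thresholds, with tied scores grouped into a
single step and AUC by the trapezoid rule (equivalently, concordant-pair
fraction with half credit for ties — an equivalence the tests verify
exhaustively at small n). Multi-run comparisons intersect call tables on
(position, minor allele) and classify substitutions into
reverse-complement-folded classes (CpG-context C→T, C→T, T→C, C→A, A→C,
G→C, other).

## Study design used in the acceptance checks

The scaled-down simulation study runs on a 16,569 bp random ancestor with
three derived templates at divergence 0.002 under the `legacy_basecaller`
profile: control spike-in at 2500× for training, an independent 1000×
control library for held-out FWSE, and ordered-pair mixtures at 4000× and
fraction 0.003 (ROC pooled over three mixtures; MAF estimates over all six,
428 truth sites). These sizes were chosen so that each group retains
enough well-populated quality bins for fitting while the full study stays
desk-scale.

A known quantitative limitation, derivable in closed form: with counted
(post-threshold) base error rate e and a uniform spectrum, the raw-count
MAF estimate at a site of depth n is X + N with X ~ Binomial(n, f) the
realized minor reads and N ~ Binomial(n, e/3) error reads, so its Pearson
correlation with the realized MAF is bounded by √(f/(f + e/3)) regardless
of depth. At f = 0.003 exceeding r = 0.99 requires e < 1.8·10⁻⁴ — an
essentially error-free counted pool. Under any planted miscalibration
strong enough for recalibration to matter, the measured correlations land
near 0.93, and the maximum-likelihood estimate shares the bound (it
corrects the bias of N, not its variance). The corresponding acceptance
test asserts the stricter historical bound and is expected to fail under
these study conditions; the bound, not the implementation, is the binding
constraint.

## Known limitations

* Overlapping mate pairs double-count the overlapped bases; a
  fragment-aware consensus of mates is not implemented.
* Recalibration assumes the user's read structure (lengths, pairing)
  matches training; unseen cycles fall back to raw scores.
* The caller models the best non-major allele only; genuinely tri-allelic
  sites surface via a flag.
* Duplicate removal is an upstream responsibility (a warning is emitted if
  duplicate-flagged reads are encountered); no mapping-quality cutoff is
  applied, mirroring the intended consensus-mapping workflow.
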