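# Methods

## Data model

A screen is a proteins × runs grid of non-negative integer spectral counts
(`SpectralCountMatrix`) with per-run metadata: role (`bait` / `control`),
condition label, replicate index. Counts are protein-level sums; rolling up
peptide identifications to proteins is assumed done upstream by the search
engine, and a missing cell means "not detected" and is stored as 0 (the
detection rule of the filter needs explicit zeros). Protein ids are opaque
strings — no accession normalization is attempted. All file I/O is UTF-8
tab-separated text with `#` comments, chosen so that write→read round-trips
are exact and result tables are byte-stable under a fixed seed.

## Replicate filter

The three rules, with defaults:

| parameter | default | meaning |
|---|---|---|
| `min_detected_replicates` | 2 (of 3) | bait replicates with count ≥ `detection_threshold` |
| `detection_threshold` | 1 count | one spectral count is the natural detection floor |
| `min_fold_over_control` | 2.0, inclusive | mean bait ≥ 2× control reference |
| `control_aggregate` | mean | control reference; `max` and `sum` are available for a stricter/looser reading |
| `max_control_count` | 10, strict | every control replicate < 10 |
| `pseudocount` | 0 | added to the control reference before division |

Interpretation choices: "at least twice" is inclusive (≥ 2.0); the control
cap is strict (< 10); the control reference is the *mean* over control
replicates, paralleling the mean on the bait side, with the max- and
sum-based alternatives exposed as options. With a pseudocount of 0 and an
all-zero control group, fold enrichment is reported as `inf` and rule 2
passes whenever any bait count is positive — zero-background preys are the
strongest hits and must not be dropped; a pseudocount can be supplied when
finite folds are wanted for reporting. The fold comparison at the boundary
is exact in IEEE arithmetic (the ratio of two replicate means is computed
so that a mean exactly twice another yields exactly 2.0; the test suite
checks the filter against an exact rational-arithmetic evaluator).

The filter is applied per condition independently, each condition with its
own bait/control triplicates.

An important property, measured rather than assumed: against a sparse
Poisson background present in bait and control alike, the rule filter is
*sensitive but not specific*. With background rate 0.8 per run, a
background protein is detected in ≥ 2 of 3 bait runs with probability
~0.58, and conditional on that passes the twofold rule ~40% of the time —
mostly because its three control counts are all zero with probability
e^(−2.4) ≈ 0.09, which makes the fold infinite. The candidate list
therefore carries an observed FDR around 0.7 on the default synthetic
screen even though sensitivity is ~0.95. This is inherent to the rules,
not an implementation artifact, and it is why the probabilistic score
follows the filter in the pipeline.

## Interaction probability (AvgP)

A deliberately transparent, single-bait version of the spectral-count
interaction-scoring idea: per prey, a two-component Poisson mixture with

* λ₀ = max(mean control count, `lambda_floor`=0.1) — the floor keeps the
  background likelihood proper when controls are all zero;
* λ₁ = max(mean bait count, `true_rate_factor`·λ₀), `true_rate_factor`=2 —
  the "true interaction" component always means at least twice the
  background rate;
* prior π = `prior_true` = 0.1 — roughly the fraction of detected proteins
  expected to be genuine proximity partners in a typical screen.

The per-replicate posterior is computed in log space
(`logaddexp`), so counts in the hundreds against tiny rates do not
underflow; the score is the arithmetic mean over bait replicates. Rates
are plug-in means with floors rather than EM estimates: deterministic,
inspectable, and sufficient for ranking. Consequences worth knowing:

* λ₁ = λ₀ (e.g. `true_rate_factor`=1 and bait mean ≤ λ₀) collapses the
  likelihood ratio to 1 and the posterior to the prior exactly.
* All-zero bait counts give AvgP ≤ π.
* For λ₁ > λ₀ the posterior is monotone increasing in the count (the
  Poisson log-likelihood ratio is linear in x).
* A contaminant with high counts in both groups gets λ₀ ≈ λ₁/2 ≈ its own
  abundance, a likelihood ratio far below 1 at its typical counts, and a
  near-zero posterior — which is exactly how the score outranks raw
  bait-mean ranking when contaminants are present.

The high-confidence cutoff is AvgP > 0.75, strict. Because published
scores of this family depend on implementation and options that are rarely
fully specified, per-protein score values from other tools are not
comparable; only the cutoff semantics and the ranking behavior are
guaranteed here, and those are what the tests measure. One replicate lost
to dropout pins AvgP near 2/3 even for a strong prey, so the 0.75 cutoff
effectively demands consistent evidence in all three replicates — the
high-confidence set is small and clean rather than exhaustive.

## Differential proximity

Two screens rarely have comparable depth (total identified spectra can
differ by >50%), so cross-condition ratios use total-count normalization:
each bait run's counts are divided by that run's column total, averaged
over the condition's bait replicates, then rescaled by the mean bait
column total of the whole study so values stay on a count-like scale. The
rescaling is a single global factor; ratios between proteins are invariant
to any per-run depth change. A pseudocount of 0.5 on both sides of the
ratio keeps it finite for preys absent in one condition.

The partition of two candidate lists is pure set algebra (common /
specific-to-A / specific-to-B, always summing to the union). Common
proteins with (normalized A + 0.5)/(normalized B + 0.5) strictly above 5
are flagged enriched in A, and symmetrically for B. No replicated variance
model is fitted — with triplicates of over-dispersed counts the threshold
rule is what screens of this kind actually report, and the flags should be
read as candidate calls, not significance statements.

## Term enrichment

Standard over-representation: for a term with K background members, k of n
candidates inside, background N, the p-value is the hypergeometric upper
tail P(X ≥ k) (scipy), fold enrichment (k/n)/(K/N), and q-values are
Benjamini–Hochberg across terms (statsmodels). The background is the set
of proteins detected in the relevant screen — the only background the data
can justify; testing against a whole proteome inflates every fold. Terms
are intersected with the background before counting, and terms with fewer
than `min_term_size`=2 background members are dropped. GO-graph
propagation and term redundancy reduction are out of scope; supply any GMT
you like.

## Synthetic screens

The generator draws, for each condition and role, a proteins × replicates
block:

| class | bait runs | control runs | default size |
|---|---|---|---|
| background | Poisson(0.8) | Poisson(0.8) | 500 |
| true interactor | NB(mean 12·multiplier, size 2), 10% dropout | Poisson(0.8) | 40 |
| contaminant | Poisson(25) | Poisson(25) | 15 |

Defaults mirror the scale of a real polarity-protein BioID screen:
~550 detected proteins, triplicate bait and control purifications, two
culture conditions ("2D", "3D"). Five of the 40 true interactors carry a
25× multiplier on their bait mean in the 3D condition. The multiplier was
fixed by an a priori power analysis: with negative-binomial size 2 and
three replicates the log of the observed normalized ratio has an sd near
0.6, and total-count normalization itself shrinks the observed ratio (the
enriched proteins inflate their own condition's depth), so a true effect
near the 5× calling threshold is recovered less than half the time;
25× gives ≈90% power for "≥80% of enriched preys flagged" while keeping
the enriched subset the small minority that real screens show.

Deliberate mismatches with the scoring model: true-interactor bait counts
are negative-binomial (over-dispersed) although the scorer assumes
Poisson, and dropout zeroes a bait replicate with probability 0.1 —
recovery numbers therefore measure robustness, not best-case fit.
Contaminants are drawn identically in bait and control, the situation the
control cap exists to remove; P(Poisson(25) < 10) ≈ 5·10⁻⁴ per replicate,
so essentially every contaminant trips the cap in at least one of three
control runs.

What the generator does *not* emulate: protein-length and abundance biases
in spectral counts, correlated background across runs (batch effects),
peptide-level identification noise, or shared contaminant structure across
unrelated baits (CRAPome-style frequencies). Recovery results on synthetic
screens bound what the pipeline can do when its distributional picture is
roughly right; they do not certify performance on any particular real
dataset.

`evaluate_recovery` reports sensitivity |P∩T|/|T| and observed FDR
|P\T|/|P| for a predicted set P against true set T, and for ranked
predictions the area under the sensitivity vs observed-FDR path traced by
sweeping every distinct score threshold (trapezoidal, anchored at (0,0);
tie groups enter together). The area is a comparison device between
rankings of the same universe, not a calibrated probability.

## Determinism and numerics

All randomness flows through one integer seed into
`numpy.random.default_rng`; the pipeline manifest records parameters,
library versions and per-stage counts, and omits timestamps, so a rerun
with the same config is byte-identical. Result tables are written with
`%.6g` float formatting. Posteriors are computed in log space; the
hypergeometric tail uses scipy's exact implementation (validated in the
tests against exhaustive draw enumeration up to N = 12); BH is validated
against an independent step-up implementation.

## Scope and sizes

The default synthetic screen (555 proteins × 12 runs) is the package's
standard benchmark; every recovery figure in the tests and the acceptance
script is computed at that size, where the full pipeline runs in a few
seconds. Reproducing a published screen's exact candidate counts requires
that study's supplementary spectral-count tables as input; the package
ships no third-party data.
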