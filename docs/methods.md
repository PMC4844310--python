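# Methods

## Problem setting

Given several independently designed expression experiments — each a genes
× samples matrix of RMA-style log2 values with per-sample tissue, stage
(days after pollination, DAP), genotype and replicate annotations — the
package answers two questions:

1. **Coexpression meta-analysis.** Which genes are tightly, *mutually*
   coexpressed with a small set of bait genes consistently across the
   experiments? (Candidate partners in a common developmental pathway.)
2. **Exclusivity screen.** Which members of a gene family are expressed
   exclusively during caryopsis development, restricted to the endosperm,
   and peaking in a defined window (3–4 DAP by default)?

Input matrices are assumed already normalized on a log2 scale; the package
performs no normalization and no probe-set annotation — gene identifiers
are taken as already harmonized across experiments. Duplicate gene rows
(probe-set → locus many-to-one) are collapsed, by default keeping the row
with the highest mean signal, the usual convention for retaining the
strongest probe set; `first` and `error` policies are available.

## Mutual rank

Within one experiment, Pearson correlation is computed at replicate level
(not on condition means — replicate level preserves sample size and is the
common convention for array coexpression) over pairwise-complete samples,
requiring at least `min_pairs` (default 4) complete observations per pair.
Genes with zero variance are unrankable and excluded. For each gene the
remaining genes are ranked by decreasing raw *r* (negative correlations
rank below positive ones — the screen looks for co-regulated partners, not
anti-regulated ones), with exact ties assigned average ranks and the
self-pair excluded before ranking. The mutual rank of a pair is the
geometric mean of the two reciprocal ranks:

    MR(a, b) = sqrt( rank_a(b) · rank_b(a) ),   1 ≤ MR ≤ G − 1.

MR is symmetric and invariant under global affine transforms of the matrix
(Pearson affine invariance); it is *not* invariant under arbitrary
per-gene monotone transforms, and no such invariance is claimed.

### Cross-experiment combination

Each bait yields one MR per gene per experiment in which both are
rankable. The combined MR is, by default, the **maximum** (worst case) over
contributing experiments: a candidate must correspond closely to the bait
in every experiment where the bait is measured. The rationale is
empirical and methodological: compendium experiments differ enormously in
design, and a single experiment with few distinct conditions can produce
small MRs by chance; averaging (even geometrically) lets such
single-experiment flukes into joint-threshold candidate sets, while the
worst-case summary demands the cross-experiment consistency that the
analysis is after. `geometric_mean` (log-space average) remains available
via configuration, and the policy in force is echoed in every run report.

A gene's combined MR is only reported when the gene is scoreable in every
experiment where the bait is rankable (`min_coverage` defaults to that
count); genes with partial coverage keep their per-experiment MRs but are
flagged.

### Candidate selection

A gene enters the candidate set at threshold *T* when its combined MR is
**strictly** below *T* for **every** bait. Baits are never members. Default
thresholds are 20 (strict set) and 50 (extended set); by monotonicity the
strict set is always nested in the extended one. Members are ordered by
their worst over-baits MR, ties broken lexicographically by gene id, so
output tables are deterministic.

## Exclusivity screen

"Expressed" is decided on condition-group means (mean over the replicates
of one (tissue, stage, genotype) group), never on single samples. The rule
has three parameters:

- **expression floor** (log2): below it a group mean counts as background.
  Default: the 25th percentile of the experiment's value distribution,
  computed per experiment — robust to differing array background levels.
  A fixed floor can be configured.
- **exclusivity ratio** (default 0.15): the largest tolerated ratio of
  (off-target group rise above floor) to (best target group rise above
  floor). Zero demands literally no off-target signal.
- **target tissues** (default endosperm + caryopsis).

A gene is exclusive iff its best target group mean exceeds the floor and
every off-target group mean m_off satisfies
`m_off ≤ floor + ratio · (best_target − floor)`. The peak stage is the
argmax over target group means, ties breaking toward the earlier stage
(developmental peaks are reported at onset). Genes never measured in an
experiment containing off-target tissue receive a distinct *indeterminate*
status — they are never silently treated as exclusive — and genes absent
from the atlas are *not measured*.

Rendered labels collapse fine-grained stages onto canonical reporting
windows (before anthesis, 1-2, 3-4, 5-10, 11-20, >20 DAP) so a dense daily
time-course reads `3-4 DAP, 1-2 DAP, 5-10 DAP, endosperm` (peak window
first, then the other expressed windows chronologically, then the tissue)
rather than listing every day.

The genotype contrast (`compare_genotypes`) reports per-genotype mean ± SE
(SE = sd/√n with n ≥ 2; reported not-available for a single replicate) and
the linear fold ratio `2^(mean_B − mean_A)`; a linear-input switch bypasses
the exponentiation. No significance test is attached — the contrast is
descriptive, mirroring mean ± SE reporting.

## Synthetic atlas generator

The generator emulates the meta-analysis setting: three heterogeneous
designs —

- `TISSUE_ATLAS`: leaf, root, seedling, shoot, embryo (3-4, 5-10 DAP),
  endosperm (3-4, 5-10 DAP); 3 replicates per group (24 samples). The
  design that makes exclusivity decidable.
- `GRAIN_TIMECOURSE`: endosperm sampled daily 1–10 DAP, 2 replicates
  (20 samples).
- `REPRO_SERIES`: panicle before anthesis, stigma at anthesis, endosperm
  1 / 3-4 / 5-10 DAP, caryopsis 15 / 20 DAP; 3 replicates (21 samples).

Together they provide 41 endosperm/caryopsis samples across three
experiments with very different tissue coverage, exercising the coverage
and combination logic.

**Planted module.** Six genes (including the three baits) follow a shared
deterministic stage template in target tissues: a piecewise-linear rise
from 0 DAP to a peak at 3.5 DAP and decline to baseline by 10 DAP, scaled
per gene by `amplitude × U(0.8, 1.2)` (default amplitude 6 log2 units
above a baseline of 4.0 — a strong but realistic induction). Off-target
values sit at `baseline + leakage × scale` (leakage 0 by default, i.e.
perfectly exclusive). Replicate noise is Gaussian with sd 0.2 log2 units,
decomposed for module genes into a shared per-sample latent factor with
loading √ρ plus independent residual with loading √(1−ρ), so the pairwise
correlation of module residuals concentrates near ρ (default 0.95). The
latent-factor construction keeps the implied covariance positive
semidefinite with a single knob.

**Null control.** At ρ = 0 nothing is planted to co-vary with the baits:
the baits keep the endosperm-peak profile (they remain realistic
endosperm genes) but the other module genes degenerate to background-like
genes. Candidate counts then measure the pipeline's false-discovery
behaviour.

**Background genes.** Each of the 500 background genes draws an overall
expression level e ~ U(2, 6) log2 units above baseline and a "home"
off-target tissue where it is expressed at exactly that level; every other
(tissue, stage) group gets an independent `U(0, 1) × e` level, cached so
the gene is consistent across experiments. Anchoring every background gene
in an off-target tissue encodes the biological fact that genes which are
not grain-specific are expressed somewhere vegetative, and has a useful
formal consequence: on noiseless data no background gene can satisfy the
exclusivity rule (its off-target home group always violates the ratio test
whenever it is expressed at all), so the screen's truth-recovery is exact
by construction rather than probabilistic. An earlier design that varied
background levels smoothly along the DAP axis was rejected: broad smooth
bumps systematically resemble the planted peak template and inflate
chance candidates, which iid group levels do not.

All randomness flows from a single seeded `numpy` generator;
identical spec + seed reproduce the atlas bit-for-bit.

## Validation surface and what it does(n't) show

The test suite checks, among other things:

- equivalence of the MR computation with an independent brute-force
  implementation (explicitly sorted correlation lists) to 1e-9 on dozens
  of random matrices;
- MR symmetry, bounds and affine invariance; threshold nesting;
  single-experiment combination identity;
- planted-module recovery on the default conditions: recall ≥ 0.9 and
  precision ≥ 0.8 at joint MR < 20 in ≥ 90% of 20 seeded replicate
  atlases, with the ρ = 0 null yielding ≤ 2 candidates in ≥ 90% of runs;
- exact truth recovery of the exclusivity screen on noiseless atlases and
  the Table-style label format;
- byte-identical outputs for identical config + seed.

The generator emulates group-mean structure, replicate noise and
heterogeneous designs; it does **not** emulate probe-level artifacts,
background correlation structure among unrelated genes (real compendia
contain correlated housekeeping programs), batch effects, or missing-value
patterns. Passing the recovery criteria therefore demonstrates the
pipeline's correctness and its behaviour under the stated noise model, not
a false-discovery guarantee on real compendia — on real data the MR
thresholds act against ~10^4–10^5 genes rather than ~500, which makes a
fixed MR threshold substantially more stringent.

## Numerical and degenerate-input choices

- Correlations are clipped to [−1, 1] to absorb floating-point overshoot;
  correlation ties (exact equality) get average ranks, making rankings and
  MR values deterministic.
- Zero-variance genes and pairs with fewer than `min_pairs` complete
  observations are excluded with recorded reasons rather than propagating
  NaN silently.
- Output tables are written with 6-significant-digit floats, fixed column
  order and total row order (combined MR ascending, ties lexicographic),
  and round-trip through the provided readers to that precision.
- SE with one replicate is reported as not-available (NA), never 0.
- Stage labels order by DAP position; interval labels use midpoints
  ("3-4 DAP" → 3.5). Unknown labels fail validation rather than sorting
  arbitrarily.

## Known limitations

- The cross-experiment combination rule is a genuine modelling choice; the
  two provided policies can produce different candidate sets near the
  threshold, which is why the policy is configurable and echoed in every
  report.
- The exclusivity screen's floor and ratio defaults are decisions, not
  community standards; with array detection calls (present/absent)
  available, those would be the better "expressed" criterion.
- `screen_family` loops genes through per-gene condition profiles; for
  atlases of 10^4+ genes a vectorized group-mean pass would be the next
  optimization.
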