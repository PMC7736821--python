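# Methods

## The measurement model

2′-O-methylation (Nm) of a ribose protects the phosphodiester bond
immediately 3′ of it against alkaline hydrolysis. RiboMethSeq-style
protocols exploit this: RNA is randomly fragmented under single-hit-like
alkaline conditions, fragments are size-selected and sequenced, and the
read-end coverage at each internucleotide bond is interpreted as the local
hydrolysis rate. A coverage dip at bond *n* relative to its neighborhood
signals methylation of the ribose of nucleotide *n*, and the depth of the
dip tracks the methylated fraction of molecules.

`nmquant` implements this model both forward (a simulator that produces
fragment data from known stoichiometries) and backward (a protection score
that estimates stoichiometry from fragment-end profiles), plus a
differential layer across conditions and an orthogonal global
nucleoside-content model that mirrors LC-MS quantification of total Gm, Cm
and Um.

### Simulator

For each molecule of a reference of length *L*:

1. each candidate Nm site *n* is methylated independently with probability
   *f*(n), the site's stoichiometry in that condition;
2. each internal bond *b* = 1..L−1 is cleaved independently with
   probability *q*, except bonds 3′ of a methylated ribose, which are never
   cleaved (absolute protection; partial protection is not modelled);
3. maximal uncleaved runs become fragments; fragments with length in
   [size_min, size_max] are retained (library size selection);
4. each retained fragment contributes one event at the bond of its 5′
   boundary and one at its 3′ boundary. Molecule termini (bonds 0 and L)
   are never counted — a fragment end at the molecule terminus is not a
   hydrolysis product.

Per-sample randomness is an independent stream derived deterministically
from (master seed, CRC-32 of the sample id), so replicates differ while a
rerun with the same master seed is bit-identical.

Defaults: *q* = 0.05 per bond, 2×10⁵ molecules per reference per sample
(scaled by relative pool abundance, so a reference at 1 % of the maximum
abundance receives 1 % of the molecules — this is how rare isoacceptors end
up under-covered and gated), retained fragment lengths 10–50 nt.

**Why 10–50 nt and not a tighter tRNA-library window.** Size selection
censors boundary events: with a lower bound of *m* nt, no retained fragment
can end at a nucleotide before position *m*, so 3′-boundary counts are
impossible at bonds < *m* and jump to nonzero at bond *m*. A window of
20–40 nt puts that jump (bond 20) inside the w = 2 scoring neighborhood of
the D-loop position 18 — the most important site class — inflating the
neighbor mean and biasing an unmethylated site's score to ≈ 0.26. With
10–50 nt the censoring ramp is locally linear across every scored window,
and a symmetric neighbor mean cancels a linear trend, leaving a residual
bias below ~0.02 everywhere on the fixture. This is a property of the
scoring estimator, not of the chemistry; the bounds are configuration.

### Protection score

For site *n* with end count e(n) and neighborhood mean
ê(n) = mean of e(j) over j ∈ {n−w..n−1, n+1..n+w} (w = 2 by default):

    raw   = 1 − e(n) / ê(n)
    score = min(1, max(0, raw))

Under the simulator's uniform-cleavage model E[e(n)] = (1−f)·E[ê(n)], so
the raw score is an (asymptotically) unbiased estimator of the
stoichiometry f, which is what makes parameter recovery testable.
Neighboring bonds that are themselves candidate Nm sites are excluded from
the window by default, since a methylated neighbor depresses ê(n) and
would bias the score downward (configurable).

Entries are reported NA, with a reason, when the site is within w bonds of
a molecule edge, when the neighborhood is uncovered, or when ê(n) falls
below the coverage gate (default ≥ 10 events). The gate is the package's
explicit form of the "coverage insufficient for reliable quantification"
exclusion: on the packaged fixture the three rare isoacceptors
(abundance weight 0.02) are the references that trip it.

### Differential layer

- **Row centering** (heatmap normalization): score − across-sample row
  mean, NA-ignoring; idempotent. When replicate counts differ per
  condition this is a sample-level mean, not a mean of condition means.
- **Replicate summaries**: mean/min/q1/q3/max/n per (site, condition);
  quartiles by linear interpolation between order statistics — the
  convention is pinned because at n = 2–4 the alternatives visibly differ.
- **Welch test**: two-tailed unequal-variance t-test
  (Welch–Satterthwaite df), computed on raw (unclamped) scores when used
  inside the calibration experiment, because clamping truncates the score
  distribution near f = 0 or 1 and breaks the test's normality premise by
  construction. No multiple-testing correction by default (per-site
  replicate statistics, not a corrected screen); Benjamini–Hochberg is
  available.
- **Deltas**: condition mean − control mean in stoichiometry points. A
  ratio ("fold change") is deliberately not the default: responsive sites
  are nearly unmethylated under control conditions, exactly where a ratio
  diverges. Ratio output exists behind a flag.

### Global nucleoside content

The content of Nm species *s* (Gm, Cm, Um, Am) in a pool of references
with abundance weights a_r is the expected mole fraction

    content(s) = Σ_r a_r Σ_{sites of s on r} f_site / Σ_r a_r L_r ,

linear in f and invariant to rescaling all abundances. A site's species is
its sequence base + "m" (so cmnm5Um34 counts toward Um). The LC-MS
simulator multiplies each species' exact content by unit-mean lognormal
noise with a given coefficient of variation (default 0.05); instrument
response and calibration curves are abstracted away — content is what a
calibrated internal-standard quantification would report.

## The packaged fixture

A desk-scale stand-in for the E. coli Nm landscape: 20 candidate tRNA
sites (12 Gm18, 6 Nm32, 2 Nm34) on 19 synthetic 76-nt tRNAs, and 4 rRNA
sites on two synthetic rRNA stubs. Three rare-isoacceptor Gm18 sites are
excluded for insufficient coverage, leaving 17 measurable (9 Gm18, 6 Nm32,
2 Nm34). Named rows (the five stress-responsive Gm18 carriers, the three
rare isoacceptors, the named anticodon-loop carriers) use field
identities; the rest are placeholder isoacceptors flagged
`placeholder=True` — class counts, not placeholder identities, are the
modelled quantity. Sequences are deterministic pseudo-random RNA with the
expected base planted at each site and a CCA 3′ end; rRNA residue numbers
(1402, 2251, 2498, 2552) are display labels on stub coordinates.

The default stress scenario: responsive Gm18 sites at f = 0.05 under
control and f = 0.45 under stress (+0.4); constitutive sites at 0.5
(other Gm18), 0.8 (Nm32), 0.6 (Nm34), 0.9 (rRNA) in both conditions.

## What the synthetic data does and does not emulate

Emulated: Bernoulli per-molecule methylation, single-hit-like random
cleavage with absolute 3′ protection, size selection, abundance-driven
coverage differences, replicate-to-replicate sampling noise, lognormal
LC-MS noise.

Not emulated: ligation and PCR bias, base-composition-dependent cleavage
preferences, partial protection, interference from non-Nm modifications
adjacent to scored sites, alignment ambiguity among near-identical
isodecoders, and chromatography/ionization effects. Passing tests
therefore demonstrate that the estimators are correct and calibrated under
the stated measurement model — not that real libraries are free of the
biases above. On real data the score window, gate and the Nm-neighbor
exclusion are the knobs that absorb some (not all) of these effects.

## Experiment sizes

The packaged experiments are sized so the whole suite runs on a laptop
core in a couple of minutes: stoichiometry recovery uses 6 stoichiometries
× 3 seeds at 2×10⁵ molecules; null calibration uses 100 simulated
two-condition datasets at 2×10⁴ molecules over a five-reference sub-pool
(500 Welch tests); the perturbation and concordance experiments use 3
seeds at full depth over the Gm18 carriers. These sizes give binomial /
Monte-Carlo noise comfortably inside the asserted tolerances.

## Numerical and degenerate-input choices

- Scores are clamped to [0, 1]; the unclamped raw value is retained.
- ê(n) = 0 → NA ("zero neighbor coverage"); both group variances zero →
  Welch test refuses ("degenerate samples"); constant vectors → Pearson r
  reported NA; all-NA score rows are dropped from the centered matrix with
  a warning.
- Count-table round trips reconstruct n_fragments as ceil(sum/2), an upper
  bound consistent with the two-events-per-fragment invariant.
- Sign concordance counts a zero delta on either side as concordant.

## Known limitations

- Absolute protection means the score cannot distinguish f = 1 from a
  structurally inaccessible bond; real data need orthogonal evidence.
- The content model ignores non-Nm modified nucleosides sharing a mass
  channel; pseudouridine can be carried as a species label but has no
  sequencing-arm counterpart.
- Scoring assumes a locally flat (or locally linear) cleavage background;
  strong sequence-dependent cleavage bias would require a weighted window
  or explicit background model.
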