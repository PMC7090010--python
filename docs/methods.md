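# Methods

This note records the models, defaults and numerical choices behind
`inteinscreen`, and what the synthetic-data generators do and do not
emulate.

## Signal model and normalization

A well's fluorescence reading is treated as

    F = F_medium + OD_cells · (r_background + r_signal) · ε

where `r_*` are per-cell (Fluo./OD600-scale) rates, `OD_cells` is the
blank-corrected cell density and ε is multiplicative noise. The
normalization chain inverts this composition step by step: subtract the
arithmetic mean of the medium blanks (per plate, channel and — by
default — time point), divide by blank-corrected OD600, subtract the
negative-control mean, and aggregate replicates to mean/sd/n (sd with
ddof = 1; reported as missing, never 0, for n = 1).

Choices that matter downstream:

* **Negatives are retained.** Blank/control subtraction can produce
  negative values; clamping them at this stage would bias the medians
  the orthogonality criterion uses. Classifiers floor them at zero only
  when forming ratios.
* **OD floor.** Fluo./OD600 blows up for non-growing wells; wells with
  OD600 < 0.01 after blank correction are flagged (`low_od`), not
  dropped, so failed cultures stay visible.
* **Kinetic blanks.** Blank subtraction is per time point by default
  (`per_time=False` applies a single pre-read blank), since the medium
  signal can drift over a 20 h run.

## Orthogonality criterion

For a k × k matrix, each pair contributes 2(k−1) cognate-normalized
non-cognate values (46 at k = 24). A pair is orthogonal iff
max < `max_threshold` (0.2) and median < `median_threshold` (0.05),
both strict ("below"), the even-length median being the mean of the two
central values. Two non-cognate policies exist because split variants
of one parent intein often share sequence and cross-react by
construction: `all` (default; counts every off-diagonal cell, matching
the 46-value bookkeeping) and `exclude_same_intein`. Neither is claimed
to be "the" field convention; both are exposed.

**Hereditary vs non-hereditary rules.** Restricting a matrix to a
subset removes values from every member's non-cognate list, so each
member's *max* can only stay or fall — the max rule is hereditary. The
*median* is not: deleting small values can raise the median of the
remainder, so a pair orthogonal in the full matrix can in principle
fail in a sub-matrix. Consequences:

* The exact subset search (`max_orthogonal_subset(mode="exact")`) is a
  branch-and-bound that prunes **only** on the max rule (as a conflict
  graph whose independent sets are the max-feasible subsets) and
  re-checks the full two-threshold criterion at every visited subset.
  It is verified against exhaustive 2^k enumeration for k ≤ 10 and
  capped at k = 25.
* The restriction-monotonicity property is asserted in tests for the
  max rule only.

**Greedy pruning.** `prune_mutually_orthogonal` removes one failing
pair per round until all survivors pass. The offender is chosen by
(1) number of remaining partners it is in max-rule conflict with,
(2) max_rel, (3) median_rel, (4) lexicographic pair identity. Ranking
by conflict degree first is essential under measurement noise: a single
promiscuous pair puts one high cell into *every* other pair's list, and
with replicate noise an innocent pair's inflated copy of that shared
cell can exceed the violator's own maximum — degree (k−1 for the
violator vs ~1 for innocents) identifies the culprit regardless.
Surviving split variants of one parent intein are then collapsed to the
variant with the highest cognate signal. All tie-breaks are
deterministic.

## Densitometry

No universal formula exists for blot-based splicing efficiency; the
implemented definition is the simplest one consistent with dual-antibody
averaging: per channel × membrane,
`spliced / Σ(intensities of species that antibody detects)`, averaged
over the (typically 4) quantifications. Which species an antibody sees
is an explicit epitope map; the default includes cleavage by-products
in the denominator (N-side products for the anti-reporter-N antibody,
C-side for anti-His), and a narrower precursor+spliced map is a one-line
configuration. A zero denominator in any quantification yields a
"not detected" outcome rather than a number. Efficiencies are invariant
to per-channel×membrane exposure rescaling by construction.

## Activity and kinetics

All activity rules are strict threshold decisions: cis-splicing at
> 2000 a.u. Fluo./OD600; in vitro at > 4000 a.u. end-point fluorescence
**and** spliced product > 10 % of the cohort maximum. A reaction is
*fast* when its linearly interpolated value at 1 h exceeds 75 % of its
plateau, where the plateau is the **observed** series maximum (the
classification operates on measured curves; the fitted asymptote is
available separately from the model fit). The first-order model
A(1 − e^(−k(t−d)₊)) absorbs the lag between splicing and detectable
fluorescence in the maturation delay d (fitted, bound ≥ 0, or held
fixed); fitting uses `scipy.optimize.curve_fit` with the half-rise time
seeding k, and refuses constant series (k unidentifiable) and series of
fewer than 4 points.

## Condition screen

The screen grid is pH {8, 9} × NaCl {100, 300, 500} mM × temperature
{4, 21, 30, 37, 42} °C (DTT fixed at 2 mM as a protocol constant).
"Optimal for simultaneous use of any combination" is operationalized as
max–min: rescale each intein to its own maximum, score each condition
by its worst intein, rank descending (ties: median score, then
lexicographic condition). `median` and `mean` aggregates are provided
for sensitivity analysis; the selection is always reported together
with its rule.

## Assembly planning and yield ladders

One-pot plans assign one distinct orthogonal intein per junction
(n units → n − 1 inteins, n unit designs); solid-phase plans alternate
two inteins (designs saturate at 4 for n ≥ 4; n − 1 cycles). Product
composition sums unit repeat counts (3 G5 + 2 E per SasG5³E² unit);
masses are average-isotopic (ProtParam) for the concatenated extein
chain — one polypeptide, one terminal water, inteins excluded — reported
to 0.1 kDa. Anomalous gel migration of SasG-type proteins is not
modelled. Junction compatibility is an exact match of the realized
−3..+3 residues against each intein's preference, with no scoring.

Yield ladders assume independent per-junction success probabilities.

* *Solid phase*: a failed cycle permanently truncates the resin-bound
  chain (the simplest reading of a ladder that persists across cycles);
  species j < n has abundance (Π_{i<j} p_i)(1 − p_j), full length
  Π p_i.
* *One pot*: `simulate_yield` reports the exact distribution of the
  number of spliced junctions (Poisson-binomial, computed by
  convolution; rung s + 1 units for s successes). The per-molecule
  molar fragment distribution — what a stained lane approximates — is a
  distinct quantity exposed as `one_pot_fragment_distribution`
  (closed form over maximal runs, O(n²), equal to exhaustive
  enumeration). Both have brute-force enumeration oracles in the test
  suite, and the seeded stochastic mode agrees with the deterministic
  distributions within 3 standard errors at 10⁵ draws.

## Logic circuits

Gates are pure Boolean ANDs (trans-splicing reconstitutes the split TF
only when both halves are expressed); reporters OR over their gates.
Leakiness, dynamic range and expression kinetics are deliberately out
of scope — the model answers wiring questions (truth tables, 2^n input
enumeration in binary order), not dose-response ones.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic functions of a `GeneratorConfig` (all
draws from `numpy.random.default_rng(seed)` in fixed order; file
writers use fixed float formats, so identical configs give byte-identical
files). Defaults encode the emulated study conditions: 16 parent
inteins contributing 24 split pairs, 3 biological replicates, cognate
signal 20 000 a.u. with 10 % replicate CV (multiplicative lognormal —
plate and blot signals are positive with roughly constant CV), medium
blank 100 a.u. / 0.04 OD, negative-control background 300 a.u./OD,
Gaussian OD noise, exponential non-cognate cross-talk with mean 0.01
(sparse, like real orthogonality matrices), kinetics at 1.4 h⁻¹ with a
20 min maturation delay sampled every 5 min 24 s for 20 h, and band
tables at 90 % efficiency with 5 % noise. Planted violators overwrite a
pair's whole row and column with a chosen relative level.

What passing recovery tests shows: the pipeline inverts its own
generative model — normalization arithmetic, criterion bookkeeping,
selection and fitting are correct under realistic noise magnitudes.
What it does not show: robustness to effects the generator omits —
expression/solubility differences between chimeric constructs, growth
defects correlating with signal, spatial plate effects, non-lognormal
outliers, antibody cross-reactivity on blots, or any biophysical basis
of cross-talk. Conclusions about real screens still require the
controls the workflow itself prescribes (blanks, negative controls,
replicates, blot confirmation of unexpected fluorescence).

Problem sizes used by the test suite and acceptance script — 200
synthetic 24 × 24 matrices at the signal level plus single full
plate→matrix runs, 1000 densitometry draws, 50 subset-search instances
at k ≤ 10, 10⁵-draw stochastic ladders — were chosen as the smallest
sizes at which the Monte-Carlo assertions (≥ 99 % call accuracy,
±0.02 efficiency recovery, 3σ agreement) are statistically meaningful.

## Known limitations

* The orthogonality criterion operates on replicate means; per-replicate
  uncertainty propagation into max/median is not implemented (replicate
  sets can be attached to a matrix but are not yet consumed).
* The exact subset search's worst case is exponential; beyond k = 25 it
  refuses and suggests the greedy path.
* Solid-phase failures are modelled as permanent truncation; re-entry
  of a stalled chain in a later cycle (same missing junction, fresh
  extract) would shift the ladder upward and is not modelled.
* One-pot by-product re-equilibration over long incubations is out of
  scope; the ladder reflects a single round of independent junction
  outcomes.
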