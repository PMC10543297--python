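# Methods

## Overview

`zeppi` scores a structural model of a protein dimer by asking whether
the residues it places in contact show more coevolution and conservation
— measured on a species-paired MSA — than randomly chosen surface
residues of the same two proteins. The output per model is a set of
twelve metric Z-scores and their maximum, the final score. The method is
deliberately interface-local: all evolutionary statistics are computed
only on the alignment columns of interfacial (and null-sampled surface)
residues, which keeps the cost independent of protein length and lets
shallow alignments contribute usable signal.

## Structure processing

Models are read from PDB or mmCIF (first model only; no assembly
expansion). Hydrogens, waters and hetero ligands are removed; alternate
locations resolve to the highest-occupancy atom; selenomethionine is
treated as methionine, other non-standard residues map to `X` and are
excluded from metrics. Residue identity is (author residue number,
insertion code).

Accessible surface area uses the Shrake–Rupley algorithm (960 sphere
points, probe 1.4 Å, element van-der-Waals radii) for each chain in
isolation and in the complex; buried ASA is their difference floored at
zero. A residue is *surface* when its isolated-chain ASA reaches 5% of
the residue-type theoretical maximum (Tien et al. 2013) — the threshold
is configurable; 5% is permissive on purpose, since the null pool should
exclude only genuinely buried core. Element radii (rather than united
group radii) are used so that reduced representations, including the
synthetic single-atom fixtures, remain computable; absolute ASA values
therefore differ slightly from united-atom conventions, which is
immaterial because ASA enters only through thresholds and differences.

A contact is a residue pair from different chains whose minimal
heavy-atom distance is strictly below 6.0 Å (configurable). An interface
additionally requires buried ASA > 0 on the participating residues in
practice; the distance criterion dominates and geometry pathologies are
rare.

Structure residues map to MSA query positions by global alignment
(BLOSUM62, gap open 10 / extend 0.5, free terminal gaps). Mappings below
30% identity over the aligned region are rejected as a
sequence/structure mismatch.

## Paired MSA

Each chain brings one alignment whose first record is the query. The
alignment is reduced to the query's match columns, so column index
equals query position; A3M lowercase inserts are removed accordingly.
Species labels come from a configurable header regex (default UniProt
`OX=<taxid>`); unlabeled non-query rows are dropped and counted. Per
species, the row with the highest ungapped identity to the query is the
representative (first in file on ties).

Pairing takes the species intersection and concatenates the two
representatives per species. Filters run rows-then-columns (the order is
a package choice; the alternative order differs only on contrived
inputs): a row is kept iff it covers ≥ 50% of the surface/interface
positions of *both* proteins; then any in-scope column with strictly
more than 50% gaps among kept rows is dropped. Contacts whose columns
are dropped are excluded from scoring (reported); a model whose contacts
all drop is unscoreable. The paired depth `N_MSA` is the row count after
filtering — unweighted; no redundancy down-weighting is applied by
default, matching the depth accounting the score is calibrated for.
Homodimers self-pair each row, so their effective depth is that of the
single MSA.

## Metrics

All metrics use unweighted frequency counts over the 21-state alphabet
(gap = 21st state), natural logarithms, and the convention 0·ln 0 = 0.
For columns a (protein 1) and b (protein 2):

- `MI(a,b) = Σ p(x,y) ln [p(x,y)/(p(x)p(y))]` — nonnegative, no
  pseudocount.
- `Con(a,b) = 1 − S(a,b)/(2 ln 21)` — 1 for a doubly invariant pair, 0
  for the uniform 441-state joint. The 2·ln 21 normaliser makes Con span
  exactly [0, 1].
- `DI(a,b)`: mean-field direct coupling analysis fitted over the
  interface (plus currently sampled surface) columns only. Pseudocount
  λ = 0.5 on single and pair frequencies; connected-correlation matrix
  in the 20-dimensional reduced representation per position (gap is the
  reference state); couplings are the negated inverse; per pair, a
  two-site distribution with single-site terms fitted by fixed-point
  iteration (≤ 500 iterations) so its marginals reproduce the
  pseudocounted frequencies within 1e-4. DI is then the KL divergence of
  that distribution from the product of marginals — nonnegative by
  construction. A singular correlation matrix raises the pseudocount
  (warned); a non-convergent two-site fit reports the pair's DI as
  missing, and missing values are excluded from aggregation and APC
  averages. DCA is computed for homodimers by default (where paired
  depth is large and its contribution established) and can be forced on
  or off.

APC: over the full iface1 × iface2 matrix of a metric,
`APC(a,b) = ⟨m(a,·)⟩⟨m(·,b)⟩/⟨m(·,·)⟩` and `m_APC = m − APC`. The grand
mean in the denominator is the whole-matrix mean; a zero grand mean
makes the correction vanish, and a 1×1 matrix corrects to exactly zero
(degenerate, flagged).

A residue participating in several contacts contributes once per
contact: aggregation (mean, top) is contact-indexed.

## Null model and Z-scores

Per model, 100 fake interfaces are drawn (seeded): for each chain, a
uniform injective map from its interfacial residues into the
non-interface surface residues, falling back to all non-interface
residues when the surface pool is smaller than the interface. The real
contact topology is carried through the substitution, so a residue with
two partners keeps one substitute in two fake contacts. The pool is
restricted to residues mapped to retained MSA columns — a fake contact
must be scoreable.

For each of the twelve metrics, `z = (real − μ_null)/σ_null` with the
population standard deviation over the samples. A degenerate null
(σ = 0) gives z = 0 when the real value equals the constant, otherwise a
signed cap of ±99 with a flag. Per base metric and aggregator the larger
of the raw and APC Z-scores is kept; the final score is the maximum of
those (8 Z-values without DCA, 12 with). Reports are bit-reproducible
given inputs and seed; depths below 10 rows are flagged as shallow.

Because the final score is a maximum over correlated Z-statistics, its
null expectation is not 0: on exchangeable inputs it centres near 1
(measured 1.08 ± small over 50 seeds at the default configuration), and
the acceptance suite checks that this matches a leave-one-out
Monte-Carlo estimate of the same order statistic within ±0.5.

## Decoy evaluation

All decoys of a target share chains and MSAs; the MSAs are read and
paired once, with filters scoped to all query positions so the pairing
is identical across poses. Each model is scored with a stable per-model
seed, `(base_seed·1000003 + crc32(model_id)) mod (2^31 − 1)`, making
rankings reproducible without sharing nulls between decoys. Unscoreable
models (no contacts, unmapped chains) are recorded with a null score and
excluded from ranking metrics with a count. AUROC is the normalised
Mann–Whitney rank statistic (ties averaged); success@N asks whether any
acceptable-or-better model ranks in the top N, ties broken
deterministically on model id.

## Synthetic data generator

The fixture module emulates the two signal classes an interface can
carry, under full seed control. Sequences: per column a working alphabet
of `alphabet_size` letters (default 8 — a realistic per-column effective
amino-acid diversity); each row repeats the query letter with
probability `conservation` (default 0.5) else draws uniformly from the
working alphabet; designated covarying column pairs share a fixed
bijection between their alphabets, and the partner column copies the
mapped letter with probability `fidelity`, else draws from its own
background. Consequences used by the tests: `fidelity = 0` reproduces
the surface-column law exactly (an exchangeable null), and
`fidelity = 1` with `conservation = 0` gives a planted MI of
ln(alphabet_size). Gaps are i.i.d. per cell (default 5%); the query row
is species 1 and never gapped; default depth 500. A homodimer mode
generates one protein whose planted pairs couple two columns of the same
MSA.

Structures: one heavy atom per residue (an optional backbone mode adds
four atoms per residue for ASA tests); designated contacts sit at 5.0 Å
across the interface and all other inter-chain distances exceed 8 Å, so
the designated contact list is exactly what a 6 Å extraction recovers.
Geometries that would need one chain-2 residue touching two chain-1
residues are rejected as infeasible.

What the generator does **not** emulate: phylogenetic correlation
between rows (rows are i.i.d. given the column models), realistic
amino-acid substitution matrices, correlated gap structure
(indel blocks), paralog confusion in species pairing, or side-chain
packing. Passing tests therefore demonstrate the statistical machinery —
counting, coupling inference, null calibration, ranking — not
performance on real alignments, where phylogeny inflates background
covariation and the APC correction carries more of the load.

## Problem sizes and numerical choices

The test and acceptance runs use 30-residue chains, 4 contacts, paired
depths 100–500, 100 fake interfaces, 20–50 seeded replicates, and DCA
fits over ≤ 10–16 columns — sizes chosen so the full suite re-runs in
well under a minute while every statistical assertion retains power.
Sampling 100 nulls bounds the standard error of each z at about
`sqrt((1 + z²/2)/100)`; the suite checks 100 vs 1000 samples agree
within three such standard errors.

Known quantitative limitations, measured and frozen into test bands:

- The naive mean-field inversion overestimates strong couplings (about
  1.3× at Potts coupling 0.5 in zero-sum gauge), so two-site DI exceeds
  MI by up to ~2× at moderate coupling; DI is used as a *ranking*
  statistic, which is unaffected.
- With pseudocount λ = 0.5, the finite-sampling DI floor for independent
  columns at depth 2000 is ≈ 0.03 (max over 45 pairs) — the pseudocount
  places probability on unseen states and the inversion amplifies
  sampling noise of the 441-cell joint. Planted couplings at realistic
  strength sit an order of magnitude above this floor (top-1 recovery
  100% in the acceptance run); analyses that need a lower absolute floor
  require deeper alignments or a larger λ.
- ASA values depend on the radii set and sphere count; agreement with an
  independent Shrake–Rupley implementation at matched settings is within
  1 Å² per residue, and ASA enters the method only through thresholds
  and differences.

## Open design choices made here

- Filter order rows-then-columns; coverage boundary kept at exactly 50%,
  gap boundary dropped strictly above 50%.
- APC grand-mean normaliser (whole-matrix mean), not per-protein means.
- The gap state participates in the DCA inversion via the reduced
  representation (gap as reference) rather than being collapsed.
- Fake interfaces resample per residue (not per contact), injectively
  per chain, without replacement within a sample.
- The empirical null is the method; no analytic null is provided.
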