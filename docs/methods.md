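# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `drugsig`. It describes what the code computes; every
number quoted here is produced by the test suite or `scripts/acceptance.py`
at run time.

## Interaction scoring

A compound–protein pair is scored from the compound's binary substructure
fingerprint and the protein's predicted binding sites, each site carrying a
confidence score in [0, 1] and a set of predicted-ligand fingerprints. The
scoring rule scans all (site, ligand) pairs, selects the pair with the
**maximum Tanimoto coefficient** to the compound, and combines that maximum
with the selected site's confidence:

* `product` (default): `score = T* × w*` — preserves [0, 1] and rewards both
  chemical match and site confidence;
* `tanimoto_only`: `score = T*`;
* `sitescore_weighted`: `score = 0.5 T* + 0.5 w*`.

Ties in the maximum Tanimoto are broken by higher site score, then by
lexicographically smaller site id, so results are bit-reproducible. The
Tanimoto of two empty fingerprints is defined as 0 (not NaN) so signatures
stay finite. Fingerprints are fixed-length bit vectors; when compounds come
as SMILES the documented default encoding is a Morgan circular fingerprint,
radius 2, 2048 bits.

A subtlety worth recording: because the rule selects the *best chemical
match* and only then multiplies by that site's confidence, adding a ligand to
a **low**-confidence site can lower a product-protocol score (the new ligand
can steal the best-match selection from a high-confidence site). Monotonicity
under ligand addition therefore holds for the top-confidence site under
`product`, and for any site under `tanimoto_only`; the property tests assert
exactly that. This is a direct consequence of the max-then-weight rule, not a
defect of the implementation.

The matrix builder vectorises the computation (integer popcount matrix
products per protein) but is tested for exact equality against the scalar
per-pair rule and against an independent brute-force enumeration oracle.

## Signature comparison and ranking

Signatures are compared by cosine distance `1 − u·v/(‖u‖‖v‖)`, computed on
the columns of an explicit proteome panel (the full proteome by default —
panel choice is a required, explicit parameter because results depend on
it). An all-zero signature raises an error rather than producing NaN: it
signals that a compound scored zero against every panel protein upstream.
A query compound is excluded from its own ranking (its self-distance of 0
would trivially occupy rank 1); distance ties are broken lexicographically
by compound id and ranks run 1..N−1. Multi-query aggregation reports
similarity as `1 − distance` (higher = more similar), per-query and mean
ranks, and a library-mean control: each query's mean similarity to all
non-query compounds.

## Benchmarking and random controls

For every indication with at least two approved drugs (smaller indications
are excluded with a log message, never an error), each approved drug queries
the approved-compound comparison set; the drug counts toward `c` at cutoff
`k` if at least one co-approved drug ranks within the top `k`. Indication
accuracy is `c/d × 100`; the headline statistic is the unweighted mean over
indications (a d-weighted mean is also emitted). Comparing against approved
compounds only is the benchmarking protocol proper; ranking the full library
(`approved_only=False`) is available for candidate-generation parity.

The random control is computed two ways and both are reported:

* **analytic**: a drug with `d−1` partners uniformly placed among the other
  `N−1` ranks recovers at least one within top-`k` with probability
  `1 − C(N−d,k)/C(N−1,k)` (hypergeometric tail at zero); cutoffs spanning
  the whole set give 100% and are logged;
* **Monte-Carlo**: i.i.d. uniform sort keys per replicate simulate a random
  permutation; the replicate-level average accuracy yields a mean and
  standard error. The tests require agreement with the closed form within
  3 SE at 2000 replicates.

## Synthetic data

The generator produces every input the pipeline consumes, with planted
ground truth recorded in a `truth` record, so downstream stages can be
tested against known answers.

**Library and world.** Defaults are one tenth of a realistic screening
study: 245 approved + 1077 experimental compounds, 532 proteins, 256-bit
fingerprints, 40 indications of 2–6 drugs. Each indication owns a scaffold
bit-set (~19% of the fingerprint length); a member compound inherits it with
probability `scaffold_share_prob` (default 0.75) on top of 6–12% private
random bits, and every bit is then flipped with `noise_bit_prob` (default
0.01). Indication memberships are sampled without replacement across
indications while the approved supply lasts, so planted memberships are
disjoint and unambiguous (40 × 6 ≤ 245 at the defaults); once exhausted,
drugs are reused. Binding-site ligands are, with probability one half, exact
copies of a random library compound's fingerprint — "true binders" that make
chemically similar compounds score high at that protein — and otherwise
random bits; site confidences are Uniform(0, 1), which exercises the full
range of the scoring combiner. All randomness flows through NumPy PCG64
generators keyed by a single integer seed, so worlds are bit-identical
across runs and platforms.

What this emulates: the approved/experimental split, same-indication
chemical similarity, and proteins whose predicted ligands genuinely overlap
library chemistry. What it does not: real chemistry (no molecules, no 3D
structure, no realistic fingerprint bit correlations), realistic indication
size distributions, or the curation noise of real drug/target databases.
Passing tests therefore demonstrate that the *pipeline machinery* recovers
planted structure, not that any particular accuracy level transfers to real
libraries.

**Dose-response plates.** Mean response follows the four-parameter logistic
`y = bottom + (top−bottom)/(1+(GI50/x)^hill)`; untreated-control wells have
mean absorbance 1.0 (100% viability); treated absorbance is
`1 − response/100` plus Gaussian noise expressed in percentage points.
Triplicates by default, matching standard viability-assay practice. The
factorial combination generator composes two single-agent curves under Bliss
independence plus a constant planted surplus in interior cells.

**Ct tables.** One extra threshold cycle means a halving of transcript, so a
planted fold change `f` shifts the treated target Ct by `−log2 f`; every
sample carries a housekeeping measurement. At zero noise the comparative-Ct
pipeline recovers planted folds exactly, by construction.

## Dose-response fitting

The 4PL is fitted by nonlinear least squares (`scipy.optimize.curve_fit`)
on the per-well unclamped inhibition values. With a log-scale dilution the
model is parametrised in log10(GI50) for conditioning; linear dilutions fit
the concentration directly (both modes are supported because either design
occurs in practice). Initial values: plateaus from the data range, hill 1,
GI50 at the dose nearest the half-maximal response; wide bounds keep the
hill positive. The reported GI50 is **capped at the maximum tested dose**
when the fitted value exceeds it, when the fitted curve never reaches 50%
inhibition at the maximum dose, or when the fit fails to converge — in every
case the cap and its reason are flagged, never silent. Standard errors come
from the curve_fit covariance (delta method for the log-parametrised GI50).

Normalisation clamps reported inhibition to [0, 100] (the heatmap colour
scale); unclamped values are retained and used for fitting and t-tests,
since clamping would bias both.

Simulation design used by the tests and acceptance script: 8 log-spaced
doses bracketing the expected GI50 symmetrically (GI50/30 to GI50×30), the
standard way a dilution series is designed around an expected potency.
Zero-noise round trips recover all four parameters to ≤1e-4 relative (GI50
to ≤1e-6 at planted 5.0 µM); at 5% noise with triplicates the median
relative GI50 error over 100 simulations is below 10%.

## Synergy

A pair is synergistic when the potency shift — single-agent potency divided
by combination potency on the same drug's dose axis — is at least two-fold.
For factorial designs the combination potency comes from per-row 4PL refits
of the titrated drug at each fixed partner dose, using the **absolute
50%-inhibition crossing** of the fitted curve rather than the 4PL midpoint
parameter: an active partner lifts the whole row's plateau, which makes the
midpoint meaningless as a potency (the midpoint equals the 50% crossing in
the single-agent case with plateaus near 0 and 100). Crossings outside the
tested dose range are capped (never reaches 50%) or floored (already above
50% at the lowest dose) at the range edges, and the resulting shift is
flagged as a lower bound — the case that matters in practice, where an
inactive single agent (capped GI50) combined with an active partner is
synergistic by at least the computed shift.

## Comparative-Ct expression

`ΔCt = Ct_target − Ct_housekeeping` per sample;
`ΔΔCt = mean ΔCt(treated) − mean ΔCt(reference)`; `fold = 2^(−ΔΔCt)`.
The `2^(−ΔΔCt)` convention is used (one extra cycle in the treated target
means half the transcript); quoting the relative level as "2ΔCt" without
the sign, as sometimes seen, is inconsistent with the ΔΔCt difference
definition, so the standard signed convention is adopted and tested.
Conditions are compared with a two-sided two-sample Student t-test on
per-sample ΔCt (Welch's correction by flag), significance read at p < 0.05,
no multiple-testing correction. Fold changes are invariant to adding a
constant to every Ct of a sample — the housekeeping differencing cancels
per-sample offsets — and the tests assert this.

## Pipeline

Stages (simulate → score → rank → aggregate → benchmark → gi50 → synergy →
qpcr) communicate only through documented plain-text formats; the matrix
artifact is written with 17 significant digits so a cached stage reloads the
exact float64 values (reading uses round-trip float parsing). One global
seed fans out to per-stage seeds by CRC-32 of the stage name, keeping every
stage independently reproducible; the manifest records SHA-256 checksums of
all artifacts, and identical config + seed yields identical checksums.
Configs are versioned JSON with unknown keys rejected (silent typos are the
main reproducibility hazard).

## Problem sizes

The default demo library is one tenth of a realistic study (1322 compounds ×
532 proteins) and runs end to end in seconds; the test suite uses smaller
worlds (tens of compounds, ≤100 proteins) and 20-seed replications for
stochastic properties, chosen so the planted effects dominate sampling noise
at sizes a laptop handles comfortably.

## Limitations

* Scores are ligand-based only: no docking, no binding-site prediction, no
  learned scorers; proteins without plausible ligand models are only as good
  as their inputs.
* Benchmark accuracy levels on synthetic worlds do not transfer to real
  libraries; only the formulas, controls and recovery behaviour are
  validated here.
* The synergy criterion is the two-fold potency shift alone; full
  combination-index (Chou–Talalay) analysis is out of scope.
* The 4PL assumes a monotone response; biphasic dose-response data will fit
  poorly (visible in the residual diagnostics, not auto-detected).
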