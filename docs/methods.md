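# Methods

## Data model and preprocessing

All computation happens on a fixed grid of 19 time points, t = 0, 1/3, …, 6
days.  Raw recordings are long-format replicate intensities on sparse day
grids that differ by molecule kind — miRNAs on days 0/1/3/6, mRNAs on
0/3/6, proteins (Western blots) on 0/1.5/3/6 with one actin lane per
(condition, day, replicate).  Preprocessing is deliberately minimal:

- replicates are combined by the plain arithmetic mean, with missing
  replicates simply absent from the mean (no outlier rejection);
- protein intensities are divided by their lane's actin intensity before
  averaging (loading control); a nonpositive actin value is an error;
- each molecule is interpolated to the 19-point grid with PCHIP (monotone
  piecewise-cubic Hermite), which reproduces knot values exactly, preserves
  monotonicity and never overshoots the recorded range.  No extrapolation:
  a dataset must record day 0 and day 6.  Knot days are inferred from the
  data, not hard-coded, so other designs work unchanged.

Intensities are used as-is.  No between-array normalization is attempted
because the model class is invariant under per-molecule changes of units
(below), which is exactly the freedom such normalization would consume.

Profiles are keyed by (molecule, kind, condition) since a gene's mRNA and
its protein conventionally share a name (mRNA Oct4 vs protein Oct4).

## The two kinetic families

Hill impact of a regulator at level y: a = (γ·y)^c with c ∈ {1..c_max}
binding sites and affinity γ (1/intensity).  Impacts add: REP = Σ a_j over
repressors, ACT = Σ a_l over activators.  The fraction of DNA templates
committed to transcription is F = ACT/((1+ACT)(1+REP)) when the gene has
modeled activators and 1/(1+REP) otherwise; F ∈ [0,1], decreasing in REP,
increasing in ACT.

Transcription–degradation (TD): dG/dt = k_transcr·F − k_react·G·M − k_deg·G,
where M is the summed level of the architecture's miRNA(s).  Units:
k_transcr intensity/day, k_react 1/(intensity·day), k_deg 1/day.

Translation–inhibition (TI): dP/dt = k_transl·G/(1+REP_mir) − k_degP·P,
with REP_mir the summed Hill impacts of the miRNAs on the transcript;
1/(1+REP_mir) is read as the fraction of G committed to translation.

Scale invariance: replacing every upstream level x by s·x while mapping
γ → γ/s and k_react → k_react/s leaves trajectories unchanged to machine
precision.  This holds per molecule, so the unknown proportionality
constants of microarray and blot intensities cancel.

k_degP is *not* fitted.  It is pre-estimated from the downstream protein's
own profile by a log-linear fit over the late part of its declining segment
(the last ~2 days of the stretch from the profile maximum to day 6).  The
tail is used because early in the decline synthesis still offsets decay and
the log-slope underestimates the decay rate; asymptotically, once synthesis
is depleted, the slope identifies it.  Consequently the decay rate is only
well identified when the transcript (and hence synthesis) falls faster than
the protein decays — profiles that stay synthesis-dominated to day 6 yield
an underestimate, which the fitted k_transl partially absorbs.  A
configuration flag (`condition_specific_kdegp`) estimates it separately per
condition instead of sharing the wild-type value, for proteins whose
half-life may differ between conditions.

Integration is explicit RK4 at fixed step 1/30 day (10 substeps per grid
interval), with upstream levels evaluated from PCHIP interpolants of their
19-point profiles at the substep midpoints.  Both equations are linear in
the state once the upstream trajectories are fixed, dynamics at these rate
scales are non-stiff, and the fixed step keeps every fit bit-reproducible.
Transient negative excursions are clamped to zero; an excursion beyond
1e-9 aborts the candidate (separating round-off from genuine instability,
e.g. rates too fast for the step).

## Architecture families

A TD architecture holds one gene, its miRNA(s), and its repressor and
activator proteins; a TI architecture holds a gene, its protein, and 1–3
miRNAs.  Families are enumerated from a miRNA→gene prediction table and a
per-gene transcription-factor configuration:

- genes in `all_nonempty_subsets` mode contribute one architecture per
  (pair, nonempty subset of the activator pool) — 7 per pair for a 3-protein
  pool — with the configured repressors always present;
- genes in `fixed` mode contribute one architecture per pair.

Which proteins sit on the repressor vs activator side is configuration, not
code: the biology (e.g. whether Oct4 auto-activates or represses its own
gene in a given context) is genuinely ambiguous, so it must be an input.
TI families take all miRNA subsets up to `max_combo` (default 3); proteins
recorded in a single condition (the knocked-out protein vanishes in its own
knock-out) are capped at 1 miRNA, because half the data points cannot
support the larger parameter counts.  Orderings are canonical (gene, then
miRNA, lexicographic) so identical inputs give identical families.

## Parameter estimation

Generic optimizers (gradient descent, genetic search) are a poor match for
these 38-equation, 3–15-unknown nonlinear least-squares systems: slow and
initialization-sensitive.  The estimator instead exploits the structure:

1. **Hill layer by grid search.**  Each regulator's saturating factor
   a/(1+a) lies in (0,1); the search runs over a coarse factor grid
   {0.1, …, 0.9} × c ∈ {1..c_max} (c_max = 4 by default).  A (factor, c)
   choice is inverted to an affinity at a *key instant* — the time of the
   regulator's maximum observed wild-type level, where the inversion
   γ = (f/(1−f))^{1/c} / y_key is best conditioned.
2. **Rate layer in closed form.**  With the Hill layer fixed, the
   forward-discretized equations (one per grid interval per condition, plus
   the initial-condition identity: 38 for two conditions) are *linear* in
   the rates.  The nonnegative rates minimizing the pooled squared
   residuals come from NNLS (an L1 linear program is available via
   `rate_solver: l1_lp`; NNLS is the default since the objective is a sum
   of squares).  An all-zero regressor column simply yields a zero rate.
3. **Scoring.**  Each candidate is scored by integrating the full equation
   and taking the worst-condition ErrPred; the search minimizes that, which
   aligns it with the validation rule (both conditions must pass).
4. **Multi-scale refinement.**  One refinement pass re-scans factors at
   ±0.05 in steps of 0.01 around the incumbent, c fixed.

When the candidate product over regulators is small (≤ `budget`, default
2000) the search is exhaustive; beyond that it switches to deterministic
coordinate descent (sweeps over regulators, each scanned over its full
(c, factor) grid with the others held at the incumbent, up to 3 sweeps or
convergence).  An explicit `search: exhaustive` configuration instead
raises a budget error for oversized architectures.  Ties between equal
objectives prefer fewer total binding sites, then the lexicographically
smallest affinity vector.  There is no randomness anywhere in the fit.

## Validation and aggregation

Smoothed relative error at one grid point: |D̂ − D| / max(D, mean(D)) —
the plain relative error with its denominator floored at the profile mean
so near-zero observations cannot blow it up.  Global ErrPred is the grid
mean of these, ×100 (RMS aggregation available by configuration; the mean
is the default reading of a "percentage-valued" global error).  A network
is validated iff ErrPred < threshold (strictly; default 10%) in *every*
scored condition; conditions whose downstream profile is absent or
identically zero (the knocked-out protein under KO) are not scored, and a
network with no scorable condition is an error.  A pair (M, G) is
validated iff at least one fitted network containing it is validated;
verdicts record which architecture kinds validated the pair.  Validated
networks are ranked by worst-condition ErrPred, ties broken by fewer
parameters, then by architecture id.

## Synthetic campaigns

The generator emulates the structure of the motivating study so every
pipeline stage is exercised without any external data: two conditions with
GCNF ≡ 0 under KO; miRNAs in three qualitative classes — HL (strictly
decreasing from a high day-0 level), LH (strictly increasing), TR
(unimodal transient peaking at day 1 or 3) — allocated by a deterministic
largest-remainder rule with default proportions 105:78:46 (the observed
class sizes among 229 classified miRNAs); protein shapes mirroring the
blotted pluripotency factors (Oct4/Nanog falling sharply in WT and slowly
in KO, Sox2 collapsing after day 1.5, GCNF peaking at day 3); per-replicate
mean-one log-normal noise (σ = 5% by default) on positive intensities;
replicate counts 6 (miRNA), 3 (mRNA), 1 (protein, with an actin lane per
protein lane); recording on each kind's sparse day grid.

Planted interactions are forward-simulated at a fine step (60 substeps per
interval) from known parameters against the same interpolated upstream
trajectories the fitter will see.  Planted downstreams start at their
day-0 kinetic equilibrium by default: cells are at steady state before
differentiation is induced, and an out-of-equilibrium start would open
with a transient between recorded days that the sparse mRNA grid (0/3/6)
cannot represent — no admissible model could then match the interpolated
observation, making the fixture unfair to the method rather than
informative about it.  The default planted TI gene's transcript collapses
in WT (Sox2-like) so the protein decay rate is identifiable (see above).

Decoy pairs are the negative class: they appear in the target table, but
their downstream follows a strong mid-course peak (low–high–low on days
0/3/6) with zero coupling to the miRNA.  Under the configured regulators
(a GCNF-type repressor peaking at day 3 with no activators) the committed
fraction is *low* mid-course and high at the ends — exactly opposed to the
decoy's shape — so nonnegative rates cannot reproduce it and the fit fails
the 10% rule.  Measured over 100 seeded campaigns at σ = 5%, planted-pair
recall is ~96–99% and no decoy validates; noise-free planted fits score
ErrPred ≈ 1%.

What the generator does **not** emulate: probe-level microarray physics
(background, cross-hybridization, saturation), biological replicate
heterogeneity beyond i.i.d. multiplicative noise, indirect regulation
through unmodeled intermediates, and model misspecification of the Hill
forms themselves.  Passing the recovery campaign therefore shows the
pipeline is correct and well-conditioned on data from its own model class
at realistic noise and sampling sparsity — not that the 10% rule has any
particular sensitivity/specificity on real arrays.

## Problem sizes and numerical choices

The bundled campaigns use ~10 miRNAs, two planted interactions and three
decoys per seed (five architectures per campaign), which makes a 100-seed
recovery study a few minutes of CPU; the enumeration of the full study
design (364 TD networks; miRNA-subset TI families) is exercised
structurally, since fitting 5701 networks is a batch job, not a test.
Key defaults: c_max 4; factor grid 0.1–0.9 step 0.1 with one ±0.05/0.01
refinement; RK4 substeps 10; clamp tolerance 1e-9; validation threshold
10% (strict); ErrPred aggregation mean.  All are configuration, not code.

## Known limitations

- The decay pre-estimation is biased low for synthesis-dominated protein
  profiles (see above); the Sox2-style condition-specific half-life
  question is exposed as a flag, not resolved.
- Coordinate descent for large architectures finds a good, deterministic
  local optimum of the candidate lattice, not a certified global one
  (exhaustive mode exists for small searches).
- Validation is purely goodness-of-prediction; no multiple-testing control
  is applied across thousands of fits, matching the method it implements.
- The committed-fraction composition (additive impacts; the rational form
  of F) is one defensible reading of the underlying occupancy argument;
  alternatives (e.g. products of per-site factors) would change only the
  two pure functions that encode it.
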