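# Methods

`contextgem` reconstructs and evaluates context-specific constraint-based
metabolic models from transcriptomics.  This note records the models and
procedures implemented, the assumptions behind them, the tunable
parameters that matter, and the design choices made where the design was
genuinely open.

## Constraint-based backbone

A genome-scale metabolic model (GSMM) is held as a `cobra.Model`:
stoichiometric matrix **S** (m metabolites × n reactions), per-reaction
flux bounds, gene-protein-reaction (GPR) rules and a biomass
pseudo-reaction as objective.  All simulation assumes steady state,
`S·v = 0`, enforced to a residual tolerance of 1e-6 (configurable).
Standard operations — flux balance analysis (FBA), parsimonious FBA
(pFBA, two-stage: fix the objective at its optimum, then minimise Σ|v| on
the split network with fraction-of-optimum 1.0), flux variability
analysis (FVA) and blocked-reaction detection — are delegated to cobra
with GLPK.  Two wrinkles are ours:

* *FVA without an optimum constraint.*  cobra's FVA at
  `fraction_of_optimum = 0` still adds `objective ≥ 0`, which clips
  reversible objective reactions; `core.fva` clears the objective first so
  the reported ranges describe the whole admissible space.
* *Boundary metabolites.*  The SBML `boundaryCondition` flag is not
  retained by the reader, so boundary species are recognised by the
  common conventions (a dedicated `b` compartment or `_b` id suffix, both
  configurable) or an explicit id list, and their rows are deleted from
  **S** without deleting any reaction.

Exchange reactions follow the COBRA sign convention (negative flux =
uptake).  "Open exchange conditions" sets every exchange's lower bound to
−1000 (configurable); the magnitude is not dictated by anything and only
needs to exceed realistic uptake rates.  Growth-medium constraints raise
the lower bound of every non-medium exchange to `max(0, lb)`, so
secretion remains possible but only medium metabolites can be consumed.

## Transcript activity scores (TAS)

TPM expression is converted to signed activity scores against thresholds
derived from the dataset itself.  Per-transcript *local* thresholds are
quantiles (linear-interpolation definition, so bit-reproducible) of that
transcript's expression across samples; *global* thresholds are the mean
of a local threshold set.  Three strategies:

* **global** — `log2(x / g_max)`;
* **localT1** — `log2(x / l(y))` below `g_max`, `log2(x / g_max)` at or
  above it;
* **localT2** — `1 + log2(x / g_max)` for confidently active transcripts
  (`x ≥ g_max`; the +1 makes the active range start at 1),
  `log2(x / g_min)` for confidently inactive ones (`x ≤ g_min`), and
  `log2(x / l(y))` clipped to [−1, 1] in the uncertain band, where only
  the sign encodes the local call.

Numerical choices: log base 2 (the expression fold-change convention;
configurable); branch boundaries assigned to the confident outer states
(`x = g_max` is active, `x = g_min` inactive; in localT1 the tie at
`g_max` uses the global branch); the intermediate constraint to [−1, 1]
is implemented by clipping, the minimal reading; zero expression maps to
a finite floor (−10) on branches unbounded below, while the clip already
bounds the intermediate branch at −1.

A caveat worth stating: the piecewise definition is *not* globally
monotone in expression.  When a transcript's local threshold differs from
the adjacent global threshold, the score drops discontinuously at the
branch boundary (e.g. localT1 at `g_max` when `l(y) < g_max`).  This is
inherent to the threshold table, not a bug; the tests assert monotonicity
within branches and the range guarantees (intermediate ∈ [−1, 1], active
≥ 1, inactive ≤ 0), which do hold everywhere.

## Reaction activity scores (RAS) and knockouts

GPR rules are parsed by a small recursive-descent parser (AND binds
tighter than OR, case-insensitive, positional parse errors).  Numeric
evaluation replaces AND with `min` (a complex is limited by its scarcest
subunit) and OR with `max` or `sum` (best isozyme vs. additive
isozymes).  `and_fn` is also exposed with a `max` option because both
conventions circulate; the default is `min`.  Evaluation happens directly
on the expression tree without DNF expansion — equivalent for min/max,
and for `sum` it keeps each gene counted once per occurrence, which we
consider the intended reading for nested rules like `A and (B or C)`.

Genes missing from the expression data score 0 (the neutral point of the
log-ratio scale) with a warning.  Reactions without a GPR carry score 0,
are excluded from FASTCORE cores and carry no weight in tINIT.  Gene
knockouts disable exactly the reactions whose GPR evaluates false with
only that gene inactive.

## Subnetwork extraction

**FASTCORE** (LP-based, core-driven).  The core set is the reactions with
strictly positive RAS (GPR-backed only), always including biomass.  The
implementation follows the published two-LP scheme: LP7 maximises the
number of core reactions carrying at least `eps` flux; LP10 minimises the
L1 flux through non-core reactions while the activated core subset stays
at `eps`; direction flipping handles reversible core members.  `eps`
defaults to 1e-4.  Core members outside the model's flux-consistent part
are dropped with a warning.  The output always contains the effective
core and induces a flux-consistent subnetwork; it is approximately
minimal, with no global optimality guarantee (on the designed test
fixtures it does match the brute-force minimum).

**fastcc** (consistency check) combines a block LP7 pass in both
directions with per-reaction cleanup LPs; it equals the complement of the
blocked set under the `eps` activation semantics and is verified against
a naive two-LP-per-reaction oracle.

**tINIT** (MILP, score-driven).  A reaction-level simplification: binary
inclusion indicator per reaction, objective = Σ RAS over included
reactions (negative scores penalise inclusion), subject to every included
reaction carrying at least `eps` flux *in one common steady-state
distribution* (the functional-flux-state semantics of the INIT family),
with biomass protected.  Solved with HiGHS (`scipy.optimize.milp`, MIP
gap 1e-6), which is deterministic for fixed inputs.  Metabolic-task
protection beyond biomass is out of scope.

Extraction output is a binary presence vector aligned to the template;
absent reactions are knocked out (bounds 0,0), not deleted, so gap
filling can re-enable them.

## Gap filling

When an extracted model fails its growth check, a MILP finds the smallest
set of candidates whose re-activation restores flux through the objective
reaction `u`.  The whole network is split so every flux is non-negative
(splitting only exchanges would not make `v ≥ 0` valid).  Each candidate
has a binary indicator coupled by the standard big-M inequality
`M·y − v ≥ 0`; the printed pairing of the two coupling constraints in the
source formulation is internally inconsistent, and the standard pair is
the unique reading compatible with the stated semantics ("y = 1 when the
flux is active").  `M = 1e6`, tightened per split column to that column's
upper bound when finite — the same feasible set, but immune to
integrality-tolerance leakage.  "Non-zero flux" through `u` is
`δ = 1e-4 × ub(u)` (configurable).  An optional lower coupling
`Σv ≥ δ·y` can forbid spurious indicators; at a cardinality optimum they
cannot occur, so it is off by default.

Two scenarios: *intracellular* (candidates are missing internal
reactions; exchanges are never candidates and by default keep template
bounds) and *medium* (internal content frozen; candidates are the
uptake-direction exchange halves, yielding a minimal growth medium).
Alternative optima are enumerated in non-decreasing cardinality via
integer cuts, in the spirit of k-shortest elementary-flux-mode
enumeration.

## Validation

*Gene essentiality.*  Each screened gene is knocked out via GPR
propagation, biomass re-optimised with FBA, and the knockout called
lethal when the mutant/wild-type ratio falls below 0.001 (0.1%,
configurable) or the LP is infeasible.  Bounds are restored exactly
between knockouts.  Genes absent from the model are predicted
non-essential and included in scoring by default (genome-wide framing);
`model_genes_only` restricts to model genes.  Experimental calls come
from thresholding CERES scores at five thresholds evenly spaced over
[−1.5, −0.5].

*Multiclass MCC.*  Computed directly from per-class prediction counts
`p`, truth counts `t`, correct count `c` and sample count `s`:
`(c·s − p·t) / sqrt((s² − p·p)(s² − t·t))`, degenerate denominators
returning 0.  The scikit-learn implementation serves as an independent
cross-check in the tests only.

*Flux activity.*  Predicted (pFBA) and measured fluxes are discretised
into forward-active / reverse-active / null with a symmetric tolerance
band (1e-6) and compared by 3-class MCC on the reaction intersection; a
user-supplied ±1 sign map reconciles direction conventions between
measurement and model.

*Parameter importance.*  OLS of MCC on one-hot encoded grid parameters.
One reference level per parameter is dropped (alphabetically first), and
a "not applicable" level — a percentile a strategy does not use — is
*also* treated as reference, because it is an exact linear function of
the strategy indicators and would make the design singular under plain
drop-first encoding.  Remaining rank deficiency raises with the
collinear columns listed.  Coefficients come with standard errors
(statsmodels).

## Flux analysis

Fluxes are scaled elementwise by `s(x) = a/(1+eˣ) + 1` before any
statistics.  The default `a = −2` is the only value for which the map is
odd and sign-preserving — algebraically `tanh(x/2)` — taming large
magnitudes into (−1, 1) without losing directionality.  Feature selection
drops columns with variance below 1e-8 (on scaled fluxes) and keeps the
200 columns (default) with smallest one-way ANOVA p-values across label
groups, ties broken by larger F then column order.  PCA loadings are
summarised per pathway as the mean over the pathway's reactions of
`|w|/max|w|`, normalised *per component* — the reading under which the
score is invariant to rescaling a component's loading vector.  Grouped
k-fold CV partitions cell lines, not rows, so no cell line contributes
flux distributions to both train and test; PCA and the random-forest
classifiers themselves are standard scikit-learn.

## Synthetic data

The toy model generator produces the named topologies (chain, diamond,
dead end, isozyme, parallel paths, minimal medium) with recorded ground
truth; biomass reactions are single-metabolite sinks.  The expression
generator emulates a TPM matrix: log-normal values (σ = 0.5 around
10 TPM), 30% of transcripts unexpressed (all-zero rows, as for silent
genes — modelling silence per transcript rather than per entry keeps the
zero fraction exact and the planted structure recoverable), and planted
active/inactive transcript sets 8-fold above/below the background mean,
recoverable by localT2 at its default percentiles.  What a green test
establishes is therefore algorithmic correctness at desk scale; the
generator does not emulate biological covariance structure, batch
effects, isoform mixtures or genome-scale network redundancy, so no test
here speaks to predictive performance on real cancer transcriptomes.

## Known limitations

* FASTCORE is approximately minimal by construction; fixtures avoid its
  known pathological cases, and no minimality is claimed beyond them.
* tINIT here is the reaction-level simplification: no metabolic task
  list, no mRNA-absence penalty tiers.
* The exhaustive oracles are exponential and guarded (≤ 14 reactions,
  ≤ 15 candidates, ≤ 3 reversibles in the tINIT oracle).
* Essentiality uses the biomass objective only, and flux comparison is
  qualitative (3-class); quantitative flux prediction is explicitly not
  attempted.
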