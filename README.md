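# contextgem

Context-specific constraint-based metabolic models from transcriptomics.

Genome-scale metabolic models (GSMMs) describe every reaction an organism
can catalyse; any one cell type or cell line only uses a subset.
`contextgem` is a pipeline for extracting and evaluating such
context-specific models: it scores transcript activity from RNA-seq
(TPM), integrates the scores through gene-protein-reaction (GPR) rules,
extracts subnetworks with FASTCORE or tINIT, repairs non-growing models
with a minimal-cardinality MILP gap filler, and validates the results
against gene-essentiality screens and measured fluxes.  It is aimed at
systems-biology researchers who want to run and benchmark this kind of
reconstruction on their own expression panels with open tooling
(cobra + GLPK + scipy/HiGHS; no proprietary solver).

## The core machinery

With a stoichiometric matrix *S*, flux vector *v* and bounds
*lb ≤ v ≤ ub*, all analysis happens at steady state, *S·v = 0*.

**Transcript activity scores.**  Expression *x* is scored against local
(per-transcript quantile) thresholds *l(y)* and global thresholds
*g_min*, *g_max* (means of local threshold sets).  The two-state local
strategy (`localT2`) assigns

* *x* ≥ *g_max*:  TAS = 1 + log₂(*x*/*g_max*)  (confidently active, ≥ 1)
* *x* ≤ *g_min*:  TAS = log₂(*x*/*g_min*)  (confidently inactive, ≤ 0)
* otherwise:   TAS = log₂(*x*/*l(y)*) clipped to [−1, 1]

with `global` and `localT1` as simpler variants.  Reaction activity
scores (RAS) evaluate each GPR numerically: AND → min, OR → max or sum.

**Extraction.**  FASTCORE finds a compact flux-consistent subnetwork
containing the core (RAS > 0) via alternating LPs; tINIT solves a MILP
maximising Σ RAS over included reactions subject to every included
reaction carrying flux in one common distribution, biomass protected.

**Gap filling.**  On the split (all-fluxes-non-negative) network, binary
indicators *y_k* with big-M coupling *M·y_k − v_k ≥ 0* select candidate
reactions; the MILP minimises Σ *y_k* subject to *S·v = 0* and a minimum
flux through the objective reaction.  Candidates are either missing
intracellular reactions or uptake-direction exchange halves (minimal
growth medium).  Solutions are provably minimum-cardinality and can be
enumerated via integer cuts.

**Validation.**  In-silico gene knockouts (GPR propagation → FBA) are
called lethal below 0.1% of wild-type biomass or on infeasibility, and
compared with CERES-thresholded CRISPR screens via the multiclass
Matthews correlation coefficient
MCC = (c·s − p·t) / √((s² − p·p)(s² − t·t)).  Predicted (pFBA) and
measured fluxes are compared as 3-class calls (forward/reverse/null).
Parameter importance across a reconstruction grid is a one-hot OLS on
MCC.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Everything below runs on generated toy fixtures — no downloads.

```python
import numpy as np, pandas as pd
from contextgem import core as mc, fixtures as fx, omics, gpr
from contextgem import reconstruction as rc, validation as vl

# a 3-step toy pathway whose middle step has an isozyme backup (g2a or g2b)
model, truth = fx.make_toy_model("isozyme")
genes = sorted({g.id for g in model.genes})

# synthetic TPM: every gene expressed near 50, except the silent isozyme g2b
rng = np.random.default_rng(0)
expr = pd.DataFrame(
    {g: rng.lognormal(np.log(0.5 if g == "g2b" else 50.0), 0.1, 6) for g in genes}
).T.set_axis([f"s{i}" for i in range(6)], axis=1)

ts = omics.thresholds_for_strategy(expr, "localT2", p_gmax=75, p_gmin=25, p_local=50)
tas = omics.compute_tas(expr["s0"], "localT2", ts)
ras, has_gpr = gpr.ras_from_tas(model, tas.to_dict(), or_fn="max")
presence = rc.fastcore(model, gpr.core_set(ras.to_dict(), has_gpr.to_dict()) | {"BIOMASS"})
ctx = rc.apply_presence(model, presence)
report = vl.essentiality_screen(ctx, genes)
print(sorted(report.predicted_essential))

ceres = pd.Series({g: (-2.0 if g in truth["essential_genes"] else 0.2) for g in genes})
print(round(vl.essentiality_mcc(report, vl.discretize_ceres(ceres, -1.0)), 3))
```

This prints:

```
['g1', 'g3a', 'g3b']
1.0
```

`g1` (sole isoform) and `g3a`/`g3b` (complex subunits, AND rule) are
predicted essential; `g2a`/`g2b` are not, because each backs the other
up through the OR rule — matching the planted screen exactly, hence an
essentiality MCC of 1.0.  Along the way, FASTCORE kept the whole
5-reaction chain even though the weakly-expressed step `R2` scored below
the core cutoff: it is required for flux consistency of the core.

The same flow is available from the shell:

```sh
contextgem preprocess  --model model.xml --expression expr.tsv --out run/
contextgem reconstruct --model run/consistent_model.xml --ras run/ras.tsv \
                       --has-gpr run/has_gpr.tsv --out run/ --algorithm FASTCORE
contextgem validate    --model run/consistent_model.xml \
                       --presence run/presence_FASTCORE_s0.tsv \
                       --essentiality ceres.tsv --out run/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the guaranteed score ranges of the `localT2`
thresholding strategy over 100 randomly generated threshold sets and a
dense synthetic expression sweep: the largest absolute score in the
uncertain band between the two global thresholds, and the smallest score
at or above the upper global threshold (sweep including the threshold
itself).  Results are written as JSON keyed by target id.
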