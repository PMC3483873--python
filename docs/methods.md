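# Methods

## Model structure

Both cell models are deterministic reaction networks over five compartments
(extracellular, membrane, cytoplasm, nucleus, endosome) with two rate-law
families:

* mass action, `v = k₁·∏[reactants]^n − kr₁·∏[products]^m` (reverse term for
  reversible steps only);
* Michaelis–Menten, `v = k₂·Eₜ·[S]/(Kₘ+[S])`, where the enzyme total `Eₜ` is
  the summed concentration of the reaction's modifier species and
  `Vmax = k₂·Eₜ` is always derived, never stored.

The ODE system is `dx/dt = N·v(x)` with `N` the integer stoichiometry matrix
(modifiers contribute zero). Constant ("clamped") species — a drug bath, the
gene template driving phosphatase induction — have their derivative forced to
zero. All concentrations are nM internally; constructors convert at the
boundary (EGF ng/ml → nM via MW 6045 g/mol, so 50 ng/ml ≈ 8.27 nM; erlotinib
µmol/L → nM). Second-order constants are nM⁻¹s⁻¹.

### Receptor layer

EGF + EGFR ⇌ EGF·EGFR; 2 EGF·EGFR ⇌ dimer; dimer → phospho-dimer
(autophosphorylation, reversed by a receptor phosphatase). Every ligand-bound
surface form — including adaptor-bound signaling complexes — internalizes
with one EGF-dependent rate constant `k_int`; endosomal receptor either
recycles to the surface or is degraded, and internalized EGF is degraded.
EGF is depletable by default (`--clamp-egf` holds it constant); the 50 ng/ml
dose is in ~5-fold excess over the wild-type receptor pool, so depletion
shapes only the late tail.

### Downstream branches

Activation steps are Michaelis–Menten with low `Kₘ` relative to the substrate
pools (zero-order regime), deactivation steps first order. This makes the
quasi-steady activity of each layer proportional to the activity of the layer
above and nearly independent of substrate totals — which is what lets the
disease model double Ras/PI3K/Akt/STAT3 without trivially doubling every
downstream amplitude. Akt activation is mediated by the PIP3–PDK1 membrane
complex; STAT3 is phosphorylated in an explicit binding/catalysis cycle on
the phospho-receptor, dimerizes (second order), and shuttles through the
nucleus.

### ERK-level negative feedback

Two loops close on ERK. A weak loop inactivates SOS (MM in SOS with ppERK as
the enzyme). The dominant loop is a slowly induced, saturable ERK phosphatase
(MKP-type): induction is Michaelis–Menten in ppERK off a clamped gene-template
species (so the induction rate saturates once the pathway is on), the
phosphatase decays first order, and it dephosphorylates ppERK/pERK with a
small `Kₘ` (zero-order, so its capacity is a hard ceiling). This delayed
feedback is what separates the two cell states: the normal cell's transient
MEK signal is caught by the accumulating phosphatase within ~10 min, while
the NSCLC cell's stronger, sustained drive exceeds the phosphatase's
steady-state capacity, so ppERK keeps climbing until the receptor pool is
finally internalized (~25–30 min). A linear (first-order) ERK deactivation
cannot reproduce this pattern: it forces the ERK peak to track the MEK peak
with the same short lag in both cell states.

### Disease and perturbation overlays

* **NSCLC**: EGFR ×3; Ras, PI3K, Akt, STAT3 ×2 (the "nearly more than
  two-fold" expression change implemented as exactly ×2, overridable per
  scenario); autophosphorylation scaled by the mutant factor (0.01, fitted);
  every EGF-dependent internalization constant ×0.5 (the one printed number —
  the wild-type/mutant internalization-rate ratio of 2). The mutant scale
  factor is recorded as a global parameter, so the NSCLC model carries
  exactly one parameter more than the normal model. The ×3 is applied to
  total receptor (the construction rule names "the EGFR concentration"
  without distinguishing surface from total); this choice is flagged in the
  model metadata. Re-applying the overlay raises, guarding against double
  scaling.
* **PTEN loss**: PTEN's initial amount is set to zero, which nulls the
  PTEN-catalysed PIP3→PIP2 flux at every state.
* **Erlotinib**: a constant bath (dose µmol/L → nM) binds the ligand-bound,
  unphosphorylated receptor dimer reversibly and blocks autophosphorylation;
  the blocked dimer still internalizes. The effective dissociation constant
  (300 nM) is not a biochemical affinity but the competition-adjusted value
  chosen so that 10 µmol/L suppresses all three downstream peaks by well
  over half (the IC50 reading of the dose) while the residual receptor
  activity still integrates PIP3 when PTEN is absent. Dose 0 is a dynamic
  no-op.

## Parameters

Receptor binding/dimerization constants are in the range classic EGFR models
use (EGF Kd ~1 nM at `kon` 0.02 nM⁻¹s⁻¹; internalization 0.008 s⁻¹ wild
type). Protein totals are tens to hundreds of nM (receptor 0.5 nM ≈ low
10⁵ receptors/cell-volume equivalent; ERK 600 nM; PIP2 600 nM). The cascade
catalytic and phosphatase constants, the receptor recycle/degrade split, the
phosphatase-induction constants, the mutant autophosphorylation scale, and
the erlotinib Kd form the declared free subset of the calibration module and
were fitted against the bundled target set — the printed peak times (pAkt
~50 s, STAT3 dimer ~200 s, ppMEK ~500 s and ppERK ≤600 s in the normal cell;
ppMEK ~1000 s and ppERK ~2000 s in NSCLC), the two-fold internalization
contrast, and the PTEN-loss late-pAkt flag. "About"/"nearly" statements are
scored as equality within 25 % relative tolerance; "within 600 seconds" is a
bound. At the shipped defaults all eight targets pass (normal 542/585/59/201 s;
NSCLC 849/1565 s; ratio 1.94; flag 1.0), so `calibrate()` is an early-exit
pass-through; it remains available to re-fit after user edits, and with
supplementary SBML models it only evaluates the targets.

Calibration never edits topology — only constants in the free subset, via a
full model rebuild per evaluation, with seeded multi-start Nelder–Mead in
log-space (defaults 16 starts × 500 evaluations; the tests use reduced
budgets and a 300 s horizon so single-constant recoveries run in seconds).

## Numerics

LSODA with `rtol 1e-6`, `atol 1e-9 nM`, dense 1 s output grid over a 4000 s
horizon (features are reported up to 2000 s; the horizon is doubled so
sustainment and final-over-peak metrics are not truncated). Peak time is the
earliest grid point attaining the global maximum (deterministic on
plateaus); the sustainment index is the integrated fraction of the horizon
spent at or above half peak; the internalization "rate" is a log-linear
least-squares exponential fit over 0–100 s of the total-surface-receptor
observable. Negative excursions within solver tolerance are clipped to zero
and counted; a clipped fraction above 0.1 % of grid points fails the run.
Reported peak times are invariant (to the grid step) under halving `rtol`
and across LSODA/Radau/BDF. The state is clipped at zero inside the RHS, so
rates are evaluated on non-negative concentrations only.

The wild-type/mutant internalization comparison is run at equal receptor
expression (the mutant-kinetics-only variant of the normal model), isolating
the receptor-kinetic contrast from the 3-fold over-expression; the full
NSCLC model confounds the two.

## SBML

Models export as SBML L2V4 with content-MathML kinetic laws and nM/second
unit definitions; the reader accepts L2V1–L3V1, converts declared mole-based
concentration units to nM (undeclared units are assumed nM with a logged
warning), maps kinetic laws back to mass-action/MM forms when the local
parameters follow the `k1/kr1/k2/Km` convention *and* the MathML evaluates
identically on random states (1e-10 relative), and otherwise keeps the law
as an opaque expression evaluated by a restricted arithmetic interpreter.
Events, delays, algebraic/rate rules and hierarchical models raise explicit
unsupported-construct errors. Read∘write∘read is the identity on the data
model.

## What the reconstruction does and does not show

The packaged model is a reduced reconstruction (44 species, 56 reactions),
not the published 109-species network; its composition claim is therefore
checked as export/import consistency unless the supplementary SBML file is
supplied, in which case the published counts (109/117/187/1) are asserted
directly. The reconstruction reproduces the printed kinetic features and
every qualitative ordering (disease above normal at peak; erlotinib
suppressing ppERK/pAkt/nuclear STAT3; PTEN-loss pAkt dominating the intact
model pointwise and remaining at its running maximum at 2000 s; late pAkt
retained under erlotinib once PTEN is lost). Freezing the internalization
constants at wild-type values while applying all other disease edits keeps
pAkt and ppMEK peak amplitudes within ~25 % of normal and ppERK/STAT3 within
a factor of ~2 — far closer to normal than the full disease model — but the
ERK peak *time* still shifts with any sustained receptor signal because the
induced-phosphatase clock responds to signal duration; this is a known
limitation of the reduced feedback representation. Passing tests show the
model family reproduces the reported kinetics under the stated construction
rules; they do not validate the rate constants against biochemical
measurements, and no claim about clinical drug response is made or implied.
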