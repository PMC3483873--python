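# egfr-sim

Deterministic ODE models of EGFR signaling in normal and non-small-cell lung
cancer (NSCLC) cells, for systems biologists studying receptor-driven kinase
cascades and TKI resistance.

EGF binding drives receptor dimerization, autophosphorylation and
internalization; the phosphorylated receptor activates three branches that
control proliferation and survival:

* **Ras/ERK** — Grb2/SOS recruitment (direct and Shc-dependent),
  Ras-GDP → Ras-GTP exchange, Raf1 → MEK → ERK double phosphorylation, with
  ERK-level negative feedback;
* **PI3K/Akt** — receptor-bound PI3K, PIP2 → PIP3, PIP3–PDK1-mediated Akt
  phosphorylation, PTEN-catalysed PIP3 → PIP2;
* **STAT3** — receptor-mediated phosphorylation, cytoplasmic dimerization,
  nuclear import.

Reactions follow mass-action kinetics, `v = k₁·∏[reactants] − kr₁·∏[products]`,
or Michaelis–Menten kinetics, `v = k₂·Eₜ·[S]/(Kₘ+[S])` with `Vmax = k₂·Eₜ`;
the network assembles into `dx/dt = N·v(x)` (stoichiometry matrix `N`) and is
integrated with a stiff solver (LSODA by default). Concentrations are nM,
times seconds.

The **NSCLC model** applies the disease construction rules to the normal
model: EGFR over-expressed 3-fold, Ras/PI3K/Akt/STAT3 2-fold, and mutant
(L858R) receptor kinetics — slowed autophosphorylation and EGF-dependent
internalization rate constants halved. Further overlays model **PTEN loss**
(PIP3 is no longer hydrolysed, so Akt stays active) and **erlotinib**
(a constant drug bath binding the ligand-bound receptor dimer and blocking
autophosphorylation).

Models load from and export to SBML (L2V4, tolerant reader for L2V1–L3V1);
when the published supplementary SBML files are available they are used
verbatim, otherwise the packaged reconstruction with calibrated constants is
built (see `docs/methods.md`).

## Worked example

```python
from egfrsim import build_scenario, simulate, SolverOptions, standard_observables
from egfrsim.kinetics_features import extract_features, compare_scenarios

normal = simulate(build_scenario("normal"), SolverOptions())   # EGF 50 ng/ml
nsclc  = simulate(build_scenario("nsclc"),  SolverOptions())
obs = standard_observables(build_scenario("normal"))

for name in ("pAkt", "ppMEK", "ppERK", "STAT3c_dimer"):
    f = extract_features(normal.observable(obs[name]), normal.times)
    print(f"{name:13s} peak {f.peak_time:6.0f} s  amplitude {f.peak_amplitude:7.2f} nM")

comp = compare_scenarios(nsclc, normal, {k: obs[k] for k in ("ppMEK", "ppERK")},
                         labels=("nsclc", "normal"))
print(comp.to_frame()[["observable", "peak_time_nsclc", "peak_time_normal",
                       "amplitude_fold"]].to_string(index=False))
```

prints

```
pAkt          peak     59 s  amplitude   23.81 nM
ppMEK         peak    542 s  amplitude   11.33 nM
ppERK         peak    585 s  amplitude    6.04 nM
STAT3c_dimer  peak    201 s  amplitude    0.06 nM
observable  peak_time_nsclc  peak_time_normal  amplitude_fold
     ppMEK            849.0             542.0        3.449933
     ppERK           1565.0             585.0       28.984502
```

In the normal cell, Akt peaks within a minute, the cytoplasmic STAT3 dimer
around 200 s, and MEK/ERK around 540–590 s, after which everything relaxes.
In the disease model the same cascade peaks later (MEK ~850 s, ERK ~1600 s)
and much higher — ERK activation that is barely a trace in the normal cell
becomes a sustained, near-saturating signal.

## Command line

```bash
egfr-sim run --scenario nsclc-erlotinib --egf 50 --erlotinib 10 --out out/
egfr-sim convert model_in.xml model_out.xml
egfr-sim calibrate --seed 0 --out calibration.json
egfr-sim reproduce --out reproduction/
```

`run` writes trajectory CSVs, a kinetic-feature table and, for drug
scenarios, an inhibition/resistance report; `reproduce` re-runs every
scenario (one sub-directory per figure-style comparison, `Fig2`–`Fig8`) plus
the bundled kinetic-feature target suite and the qualitative dominance
checks, exiting non-zero if any check fails.

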