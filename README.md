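# csptitr

Titration analysis for protein–oligonucleotide binding: quadratic binding
isotherms with multiple independent sites, dissociation-constant (K_D)
estimation from tryptophan fluorescence quenching, binding-stoichiometry
estimation from NMR shift titrations, and chemical-shift-perturbation
(CSP) epitope mapping.

The package was built around the binding behaviour of the cold shock
protein of *Thermotoga maritima* (TmCsp), a small OB-fold protein that
binds single-stranded DNA and RNA heptanucleotides with two protein
molecules per oligonucleotide and whose affinity for thymidylate and
uridylate heptamers rises by three orders of magnitude on cooling from
growth temperature (343 K) to cold-shock conditions (303 K). Everything
is general, though: any titration of a protein against a ligand carrying
`N` independent, identical sites fits the same machinery.

## The model

The fraction of protein bound at total protein concentration `c_A` and
total ligand concentration `c_B`, with `N` sites per ligand and per-site
dissociation constant `K_D`, follows the quadratic (ligand-depletion)
isotherm

```
P_AB = (c_A + N·c_B + K_D − sqrt((c_A + N·c_B + K_D)² − 4·N·c_A·c_B)) / (2·c_A)
```

Three observables hang off `P_AB`:

* **Fluorescence quenching** — `F(c_B) = F0·(1 − q·P_AB)`; fitting
  `(K_D, F0, q)` with `N` fixed gives `K_D`.
* **Fast-exchange NMR shifts** — the observed resonance sits at the
  population-weighted average position, so the normalized shift change
  `Δδ/Δδ_end = P_AB`. At millimolar protein and nanomolar `K_D` the
  isotherm degenerates to the kinked line `min(1, N·c_B/c_A)`, whose
  breakpoint at `c_B/c_A = 1/N` reads off the stoichiometry.
* **Slow-exchange NMR intensities** — separate free and bound peaks with
  integral fractions `1 − P_AB` and `P_AB`.

Epitope mapping combines per-atom shift changes between the free and the
saturated endpoint into `Δδ_comb = sqrt(Σ (w_i·Δδ_i)²)` (weights 1.0 for
¹H, 0.14 for ¹⁵N by default), classifies residues against the
population standard deviation σ₀ of the measured values (≥ σ₀ moderate,
≥ 2σ₀ high; vanished peaks are imputed at 2σ₀), and intersects maps from
several ligands into a consensus epitope.

## Worked example

Simulate a fluorescence quench titration (5 nM protein, two sites,
ground-truth K_D = 4 nM, 1% intensity noise) and refit it with a
200-draw bootstrap:

```
$ csptitr simulate --kind fluorescence --kd "4 nM" --c-protein "5 nM" --seed 11 --out sim
$ csptitr fit-kd sim/fluorescence.tsv --bootstrap 200 --out fit
K_D = 3.885e-09 M (converged=True)
```

`fit/fit_kd.tsv` then contains the point estimates with curvature and
bootstrap uncertainties:

```
kd      3.8847591e-09
kd_stderr       1.1200329e-10
kd_bootstrap_std        1.0464731e-10
q       0.79960445
...
```

i.e. K_D = 3.88 ± 0.11 nM against a generating value of 4 nM, and a
quench amplitude of 0.80 matching the simulated 0.8.

Mapping a consensus epitope from two simulated ligand titrations:

```
$ csptitr simulate --kind epitope --seed 101 --out epiA
$ csptitr simulate --kind epitope --seed 202 --out epiB
$ csptitr map-epitope --pair epiA/free.tsv epiA/bound.tsv dT7 \
                      --pair epiB/free.tsv epiB/bound.tsv rU7 --out map
dT7: sigma0 = 0.0282 ppm, 16 interacting residues
rU7: sigma0 = 0.0285 ppm, 22 interacting residues
consensus epitope: 15 residues
```

The 15 consensus residues in `map/consensus.tsv` are exactly the 15
epitope residues planted by the generator (7, 9, 10, 12, 13, 14, 16, 28,
29, 30, 33, 37, 41, 55, 63).

The same operations are available as a library
(`csptitr.fit_kd_fluorescence`, `csptitr.fit_stoichiometry`,
`csptitr.perturbation_profile`, `csptitr.consensus_epitope`, ...); see
`docs/methods.md` for the modelling details and design choices.

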