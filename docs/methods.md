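# Methods

## Binding model

All quantitative analysis rests on a single equilibrium model: a protein
A binds one of `N` independent, identical sites on an oligonucleotide B.
Writing `c_A`, `c_B` for *total* molar concentrations, the bound protein
fraction is the quadratic-isotherm root

    P_AB = (c_A + N c_B + K_D − sqrt((c_A + N c_B + K_D)² − 4 N c_A c_B)) / (2 c_A).

The total-concentration form matters because neither experiment operates
in the free-ligand regime: fluorescence titrations run at protein
concentrations comparable to `K_D` (5 nM protein against a 4 nM
constant), and NMR titrations at millimolar protein, five to six orders
of magnitude above `K_D`. In the latter limit the isotherm degenerates
to the stoichiometric kink `P_AB = min(1, N c_B / c_A)` with breakpoint
at `c_B/c_A = 1/N` — the deviation of the exact curve from the kink is
at most `sqrt(K_D/c_A)` (attained at the breakpoint), about 0.2% for
4 nM / 1 mM.

Numerically the root is evaluated as
`P_AB = 2 N c_B / (b + sqrt(b² − 4 N c_A c_B))` with
`b = c_A + N c_B + K_D`, which is algebraically identical but avoids the
catastrophic cancellation of the textbook form when `K_D` is far below
the concentrations. The discriminant is clamped at zero (roundoff can
push it slightly negative exactly at the kink) and the result clipped to
[0, 1].

Independence of the sites is assumed throughout: the experimental
titration curves this package models are monophasic, giving no purchase
for a cooperative (Hill-type) extension, which is deliberately out of
scope. `N` is real-valued — fits legitimately return values such as
1.99 — with integer values used for forward simulation.

Observables:

* fast exchange: resonance at `P_AB δ_bound + (1 − P_AB) δ_free`, hence
  `Δδ/Δδ_end = P_AB`;
* slow exchange: free/bound peak integrals `(1 − P_AB, P_AB)`.
  Differential relaxation between the two forms is ignored — populations
  are read from integrals, not linewidth-corrected amplitudes;
* fluorescence: `F = F0 (1 − q P_AB)` with quench depth `q ∈ [0, 1]`.
  No floating baseline and no inner-filter correction are applied; both
  would trade against `q` on well-behaved quench curves and neither is
  identifiable from a single titration.

A small utility predicts the relative NMR linewidth change for a change
in molecular mass as the cube root of the mass ratio (the hydrodynamic
radius scaling of a rigid sphere of constant density): a mass doubling,
as in two proteins dimerizing on one ligand, gives a factor of 1.26.

## Fitting

Both fits use bounded trust-region least squares
(`scipy.optimize.least_squares`) with multi-start initialisation.

**K_D from fluorescence.** Parameters `(log10 K_D, F0, q)`; `K_D` is
optimised on a log scale because plausible values span picomolar to
millimolar, with 8 starts spaced over `[1e-12, 1e-3]` M and the best
local optimum kept. Intensities are normalised internally by their
maximum, making the fit exactly invariant under uniform rescaling of the
data (`F0` absorbs the scale). The site count is fixed (default 2).
Standard errors come from the Gauss–Newton covariance at the optimum;
the error of `K_D` itself is recovered from the log-scale error by the
delta method. If every start fails the result is flagged
`converged=False` rather than raising.

**N from NMR.** The residue-averaged normalized shift series is fit as
`amplitude · P_AB(c_A, ratio·c_A, N, K_D)` over `(N, amplitude)` with
`K_D` frozen at the fluorescence value. The amplitude absorbs imperfect
endpoint normalization and should come out near 1. Identifiability
requires the schedule to cross the breakpoint `1/N`; on a purely linear
rise only the product `amplitude · N` is constrained. Normalization of
experimental series follows the final-titration-point convention (divide
by the last value) rather than a fitted asymptote; the generator can do
either.

**Uncertainties.** Beyond the curvature errors, a case-resampling
bootstrap over titration points (default 1000 draws, seed 1729) gives
empirical standard deviations. Resamples with fewer distinct points than
parameters cannot constrain the fit and are redrawn with a retry cap.
No dilution correction is applied to titration schedules by default;
per-point concentration tables can express one where needed.

## Epitope mapping

Per-residue combined perturbations use the weighted Euclidean norm over
whatever atoms are available (backbone H/N, tryptophan side-chain
Hε1/Nε1, glutamine side-chain amides as separate atom records). Default
weights are 1.0 for any ¹H and 0.14 for any ¹⁵N — the conventional
amide-nitrogen scaling that puts the ~5x larger nitrogen ppm range on
the proton footing — resolved by exact atom label first, then element
letter, and fully overridable; an atom with no resolvable weight is a
configuration error, not a silent skip.

The significance threshold σ₀ is the plain population standard deviation
of `Δδ_comb` over measured residues. Residues whose resonance vanishes
at the bound endpoint (exchange broadening) are excluded from σ₀ and
only then imputed at 2σ₀ and classed `disappeared-high`; computing σ₀
first breaks the circularity the imputation would otherwise introduce.
No outlier-trimmed or iterative σ₀ is offered: the procedure being
reproduced uses a single threshold pair, and the trimmed variants would
change what "σ₀" means. Classification: `< σ₀` none, `[σ₀, 2σ₀)`
moderate, `≥ 2σ₀` high (boundary inclusive upward).

The consensus over two or more ligand maps keeps a residue iff it is
high (or disappeared-high) in at least one map and at least moderate in
every other — set-symmetric in the maps, and by construction a subset of
the union of the high sets.

Absolute σ₀ values from any particular experimental dataset are not
reproducible from first principles (they depend on the measured spectra
and the atom-weight table); the package therefore validates the
*procedure* — scaling invariance, threshold boundaries, consensus rule,
and planted-epitope recovery on synthetic data.

## Synthetic data

The generators produce the data the analyses assume, under one seeded
`numpy.random.Generator` per dataset; a fixed seed reproduces files
byte-for-byte.

Study conditions used as defaults: 1 mM protein titrated to ratio 0.625
in five equal steps (NMR); 5 nM protein with a 12-point log-spaced
schedule from 5% to 99% saturation, obtained by inverting the isotherm
in closed form (fluorescence); two sites per oligonucleotide; K_D = 4 nM
(the cold-shock thymidylate value); 1% multiplicative intensity noise;
shift noise σ = 0.03 on normalized series.

The simulated protein is a synthetic 66-residue sequence — explicitly
not the sequence of any real protein — with tryptophans at 7 and 29
(contributing side-chain Nε1/Hε1 peaks) and a proline at 57 (no backbone
amide, hence never evaluable). The planted epitope (15 residues around
the ends of strands 1–3 and the connecting loops) echoes the interface
layout of an OB-fold nucleic-acid binder.

Noise model for peak lists: per-atom background perturbations are
zero-mean Gaussian with σ = 0.01 ppm on the ¹H scale (nitrogen values
scaled by the inverse weight so both atom types contribute equally to
`Δδ_comb`); this value sits well below the perturbation scale of real
interfaces and is configurable. Epitope residues receive per-atom
endpoint changes of fixed magnitude `f × 0.01 ppm` with `f` drawn
uniformly from 3–8 per residue and random sign per atom. Peak-position
measurement noise (default 0.005 ppm ¹H-scale) is added independently
to every emitted peak. Intermediate-exchange residues are dropped while
the bound fraction lies in [0.2, 0.8] — a bookkeeping stand-in for
severe mid-titration broadening, chosen instead of any lineshape
simulation, which is out of scope.

What the generators deliberately do not emulate: peak overlap and
assignment ambiguity, temperature-dependent conformational exchange,
dilution over the titration, baseline drift and inner-filter effects in
fluorescence, and differential relaxation. Passing tests therefore show
that the estimators are correct and well-calibrated *for the stated
noise model*, not that they are robust to every pathology of real
spectra.

## Problem sizes and tolerances

Monte-Carlo studies (stoichiometry recovery, K_D recovery in the tight
and weak regimes, epitope sensitivity/false-positive rates) use 200
replicates — enough to pin replicate means to a few per mil of the
parameter while keeping the whole suite in the tens of seconds on one
core. Bisection oracles run 80–200 halvings (converged far below any
asserted tolerance). The closed-form isotherm is required to match the
mass-balance bisection oracle to 1e-10 relative over 1000 random
parameter sets spanning nine orders of magnitude in concentration and
`K_D`; its `K_D → 0` limit is checked against the kink curve with the
analytically derived worst-case gap `sqrt(K_D/c_A)` plus a small
roundoff allowance.

## Formats

Everything on disk is tab-separated text with `#` comment/metadata
lines: peak lists (`residue_index, residue_code, atom, shift_ppm`, plus
optional `intensity` and `state` columns so slow-exchange free/bound
pairs can coexist), two-column titration tables with a unit-tagged
concentration header, per-residue epitope tables, structure-viewer
attribute files, key-value fit reports and JSON run manifests. Shifts
are written to 4 decimal places (sub-Hz at common fields). Concentration
units (`M`–`pM`, e.g. `5 nM`, `0.5 mM`) are parsed on input; everything
internal is mol/L. Manifests record command, arguments, seed, config
hash and package versions, and are timestamp-free so reruns are
byte-identical.
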