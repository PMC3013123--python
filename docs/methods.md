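# Methods

## The model

`dnabreathe` simulates "DNA breathing": the spontaneous, thermally driven,
transient opening of base pairs in double-stranded DNA at physiological
temperature. The model is the extended Peyrard–Bishop–Dauxois (EPBD)
mesoscopic lattice. Each base pair *n* carries one coordinate, the
hydrogen-bond stretch y_n (Å). The potential energy is

    V(y) = Σ_n D_n (e^{−a_n y_n} − 1)²
         + Σ_{n≥1} (k_n/2) (1 + ρ e^{−β (y_n + y_{n−1})}) (y_n − y_{n−1})²

The Morse on-site term models hydrogen bonding: AT pairs (two H-bonds) get a
shallower, wider well than GC pairs (three H-bonds). The anharmonic stacking
term couples neighbours; its effective stiffness drops from k(1+ρ) toward k
as both pairs open, which makes openings cooperative and lets bubbles, once
nucleated, persist. "Extended" refers to the option of dinucleotide-step-
dependent stacking constants k_n; the shipped default is the homogeneous
single-k classical parameterization, because no consensus 16-entry table is
bundled — users supply one via config, and the ρ=0, homogeneous-k limit
recovers the classical PBD energy exactly (tested).

Default constants (all config-overridable, echoed into every output for
provenance): D_AT = 0.05 eV, D_GC = 0.075 eV, a_AT = 4.2 Å⁻¹,
a_GC = 6.9 Å⁻¹, k = 0.025 eV/Å², ρ = 2.0, β = 0.35 Å⁻¹, m = 300 amu.
These are the standard PBD-literature values for homogeneous stacking.
A sanity check rejects D_AT ≥ D_GC unless explicitly overridden.

Units are Å / amu / eV internally; the derived time unit is
t₀ = Å·√(amu/eV) ≈ 10.1805 fs. Conversions to fs/ps happen only at the
interface, which keeps the integrator free of unit factors.

## Langevin dynamics

The canonical ensemble at temperature T is sampled with a stochastic
velocity-Verlet (BBK-class) integrator: deterministic force plus friction
−γmv plus a Gaussian kick of impulse variance 2γm·k_B·T·dt per step (one
Gaussian per site per step, split across the two half-kicks; the second
half-kick carries the implicit 1/(1+γdt/2) factor). At γ = 0, T = 0 the
scheme is exactly velocity Verlet, so closed-system energy conservation
(drift ≤ 10⁻⁶ eV over 10⁵ steps) is tested directly. For a free particle
the scheme's stationary velocity variance is exactly k_B·T/m at any dt,
which matters because open (plateau) sites are effectively free.

**Time step.** The default is dt = 2 fs. The conventional ~10 fs step
passes the usual stability guard (dt·a_max·√(k_B T/m) < 0.1 internal
units) but under-resolves the steep inner Morse wall: a site returning
from the dissociation plateau arrives with several k_B·T of kinetic
energy and samples curvatures ~10× the well bottom. At dt = 10 fs this
inflates single-site opening occupancy by ~0.02–0.03 absolute and
depresses the kinetic temperature at weak friction; at dt = 2 fs the
sampler agrees with the independent quadrature oracle to well within
statistical error. The stability guard is checked where the parameters
and the config meet (simulation entry), since the config alone does not
know the Morse widths.

**Walls.** Reflecting walls at y_floor = −2 Å and y_wall = 20 Å bound the
displacement. The Morse plateau makes the unbounded single-site partition
function divergent, so *some* regularization is required; sharing the same
walls between the dynamics and the quadrature oracle makes their comparison
exact rather than approximate. Reflections mirror the position and flip the
velocity.

**Friction.** Default γ = 0.05 ps⁻¹ (weak coupling) for production
breathing profiles, so the conformational dynamics are barely perturbed.
Thermostat *diagnostics* (kinetic-temperature and Boltzmann-marginal
checks) use γ = 0.2–0.5 ps⁻¹: at γ = 0.05 ps⁻¹ the kinetic-energy
autocorrelation time is ~20 ps and the sampling error of a 100-ps
equipartition estimate is comparable to the 2 % acceptance band, which
would test luck rather than correctness. This is a diagnostic setting,
not a change to production defaults.

**Seeding.** One master seed; replica i draws from
`SeedSequence(master, spawn_key=(i,))`, so every replica stream is a pure
function of (master seed, replica index), independent of execution order or
thread count. Ensembles re-run bit-identically (tested at the level of
exported TSV bytes).

**Equilibration and sampling.** Defaults: 50 ps equilibration (discarded),
1 ns production, samples every 50 fs, 100 replicas for publication-grade
profiles. Tests and the acceptance script use 50 ps production × 20
replicas, which resolves the composition contrast described below while
keeping a full verification run in minutes on one core; the methods-level
caveat is that short runs censor the longest bubbles (see censoring).

## The quadrature oracle

For a single uncoupled site the equilibrium opening probability above a
threshold h is a one-dimensional Boltzmann integral of the Morse well
between the walls, evaluated by adaptive quadrature (relative tolerance
1e-10). This is an *independent* route to the same observable the Langevin
sampler estimates; the two are required to agree within 3 standard errors
(replica-to-replica SE) at h = 0.5, 1.0, 1.5 Å. It validates the
fluctuation–dissipation balance, the wall handling, and the sampling
machinery at once.

## Bubble detection and profiles

A bubble at (position p, length L, threshold h) is a maximal run of
consecutive sampled frames with y_j ≥ h for all j in [p, p+L). Positions
index the 5'-most base pair of the window (unambiguous for even lengths).
Detection is exact run-length extraction, verified against brute-force
per-cell scanning on random fields. Events touching the first or last frame
are censored: their true lifetime is only bounded below. Censored events
are excluded from lifetime means by default ("drop"), because on short test
runs they would otherwise bias means; the "keep" policy treats them as
observed, for sensitivity checks. Occupancy (open-frame fraction) is
unaffected by censoring.

Profiles aggregate events over (threshold × length × TSS-relative
position), with default thresholds {0.5, 1.0, 1.5, 2.1} Å and lengths up
to 20 bp. A 5-bp margin at each open chain end is excluded from reported
positions, which makes the open-boundary choice immaterial to profiles.
Occupancy is exactly non-increasing in threshold and in length (stricter
criteria hold on frame subsets); this is asserted, not estimated.
Positions use promoter numbering: the TSS is +1, its upstream neighbour
−1, and 0 does not exist.

## TSS-window summaries and the contrast verdict

A profile is reduced, at one threshold, to statistics inside and outside a
TSS-centred window: mean single-base opening occupancy, pooled mean bubble
lifetime (all lengths, event-count-weighted), and the largest bubble length
observed. The focus ratio is window/background occupancy, with edge
conventions: background 0 with window > 0 gives ∞ (fully focused); both 0
gives a neutral 1.0 and is flagged undefined.

Two profiles A and B are contrasted by ratios and one categorical verdict:
"A more TSS-focused than B" iff focus_ratio(A) > focus_ratio(B) AND window
mean lifetime(A) > window mean lifetime(B). The verdict is deliberately a
conjunction of two strict inequalities, not a statistical test — the
scientific claim it operationalizes is qualitative, and uncertainty is
conveyed by re-running with many master seeds.

The default window is ±50 bp around the TSS for promoter-scale inputs. For
the shipped 60-bp synthetic designs that window would swallow the whole
margin-trimmed profile and leave no background, so shipped-design
comparisons use ±10 bp.

## Synthetic designs

The generator stands in for real promoter inputs with known ground truth:

* **focused**: 60 bp, GC-rich (0.8) random background, one 10-bp AT-only
  block centred on the TSS — a promoter with an AT-rich TSS-proximal
  element;
* **flat**: the same background with no block — a promoter without one.

The sequence-sensitivity check runs both canonical designs (fixed
sequence realizations, design seed 0) at 300 K — 50 ps production × 20
replicas per design, threshold 1.0 Å, window ±10 bp — across 20 master
seeds that vary only the thermal noise, and records the fraction of seeds
in which the focused design wins the verdict. Under these conditions the
*focus-ratio* half of the verdict separates the designs in ~95 % of
seeds, but the *lifetime* half does not: the focused design's window mean
lifetime exceeds the flat design's in only ~85–90 % of seeds, and the
conjunction inherits that rate. The cause is estimator variance, not
physics: the flat design hosts few bubble events (at its scattered AT
sites), individual bubble episodes have heavy-tailed durations, and a
50-ps × 20-replica mean over a handful of episodes fluctuates by more
than the true AT-vs-GC dwell-time difference. The gap is robust to the
censoring policy, the sampling stride (50 fs vs 10 fs), the window
(±5 vs ±10), and per-event vs per-cell vs occupancy-weighted pooling;
longer production runs, not estimator choice, are what close it. The
verdict-rate quantity reported by the acceptance script should therefore
be read as ~0.85–0.90 at this scale, rising toward 1 as production time
grows.

Planted-bubble trajectories place rectangular plateaus (amplitude above
every default threshold) on a baseline of |Gaussian| noise clipped below
the lowest threshold, so the detector must recover planted events
*exactly* even at nonzero noise — detector acceptance is exact, not
statistical. Synthetic Ct tables are built by inverting the
comparative-CT formula, so zero-noise tables round-trip exactly.

What the synthetic designs do **not** emulate: real promoter motif
structure, CpG islands, strand asymmetry, long-range composition trends,
or any coupling between breathing and transcription machinery. Passing the
contrast check shows the pipeline resolves a composition-driven breathing
difference of the designed kind; it says nothing about any particular real
promoter pair, for which users should supply FASTA with `tss=` headers and
publication-scale run settings.

## Comparative-CT arithmetic

ΔCt_cond = mean Ct(gene, cond) − mean Ct(reference, cond); ΔΔCt =
ΔCt_treated − ΔCt_control; fold = 2^(−ΔΔCt). Replicates are averaged
arithmetically on the cycle scale, and amplification efficiency is fixed at
ideal doubling (no Pfaffl-type correction) — both are the conventions of
the comparative-CT method itself. The default reference gene is TBP.
Regulation classes use the strict two-fold rule: up iff fold > 2, down iff
fold < 0.5; fold exactly 2 is "unchanged". The threshold is exposed as
config.

## Degenerate inputs and numerical conventions

Sequences must be ≥ 2 bp (the stacking term needs a dinucleotide step);
ambiguity codes (N, …) are rejected outright rather than imputed, because
the Hamiltonian has no parameters for them. A missing TSS annotation
defaults to the record midpoint with a logged warning. Zero friction and
zero temperature are accepted as the deterministic microcanonical limit.
Profile cells with no (uncensored) events have masked lifetimes and export
an empty TSV field. Quadrature thresholds equal to a wall return the exact
0/1 limits.

## Known limitations

* The EPBD lattice has no helicoidal/twist degree of freedom, no sequence-
  dependent Morse parameters beyond the two-class AT/GC split, and no
  solvent or ion model.
* Absolute bubble lifetimes depend on the friction coefficient, which is a
  model input, not a prediction; only comparative statements between
  sequences run under identical settings are meaningful.
* Short (50-ps) runs censor the longest bubbles; publication-scale
  profiles should use ≥ 1 ns production per replica.
* The driven (THz-forced) regime is out of scope: simulations here are
  equilibrium breathing only.
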