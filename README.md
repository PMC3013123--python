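# dnabreathe

Sequence-dependent DNA "breathing" dynamics for promoter analysis:
Langevin molecular-dynamics simulation of the extended
Peyrard–Bishop–Dauxois (EPBD) lattice model, transient-bubble detection
with average-lifetime profiling anchored at the transcription start site
(TSS), pairwise promoter contrasts, and comparative-CT (ΔΔCt) qPCR
fold-change arithmetic.

## Who this is for

Researchers studying the link between a promoter's intrinsic propensity
for local strand separation and its transcriptional behaviour — e.g.
asking whether a promoter shows long-lived openings focused at its TSS,
or comparing two promoters' breathing signatures under identical model
settings — plus the small downstream qPCR arithmetic such studies use.

## The model

Each base pair n carries one coordinate y_n (Å), the hydrogen-bond
stretch. The EPBD potential is

    V(y) = Σ_n D_n (e^{−a_n y_n} − 1)²
         + Σ_n (k_n/2)(1 + ρ e^{−β(y_n + y_{n−1})})(y_n − y_{n−1})²

— a Morse well per pair (shallower for AT than GC) plus anharmonic
nearest-neighbour stacking whose stiffness relaxes as neighbours open,
making openings cooperative. Trajectories are generated by BBK-type
stochastic velocity-Verlet Langevin dynamics at fixed temperature, with
reflecting walls and fully deterministic per-replica seeding. A *bubble*
at (position, length L, threshold h) is a maximal run of sampled frames
with y_j ≥ h across all L consecutive pairs; profiles report mean bubble
lifetime (ps), occupancy, and event counts over
(threshold × length × TSS-relative position), with the TSS at +1 and no
position 0. See `docs/methods.md` for the full account.

## Worked example

Compare the two shipped synthetic designs — "focused" (60 bp, GC-rich
background, 10-bp AT block centred on the TSS) and "flat" (same background,
no block):

```python
from dnabreathe import (
    EPBDParameters, LangevinConfig, make_sequence, focused_design,
    flat_design, simulate_ensemble, lifetime_profile, compare_profiles,
)

params = EPBDParameters()          # standard PBD constants
config = LangevinConfig(           # 50 ps x 20 replicas test scale
    n_equil_steps=25000, n_prod_steps=25000, sample_stride=25,
    n_replicas=20, seed=0,
)
profiles = []
for design in (focused_design(0), flat_design(0)):
    ens = simulate_ensemble(make_sequence(design), params, config)
    profiles.append(lifetime_profile(ens, thresholds=(0.5, 1.0)))
report = compare_profiles(profiles[0], profiles[1],
                          window=(-10, 10), threshold=1.0)
print(report.render())
```

Output (seed 0):

```
TSS-window contrast (threshold 1 Å, window [-10, +10])
                                 focused          flat
  window occupancy             0.0341125        0.0079
  window mean lifetime/ps       0.889232      0.707905
  window max bubble/bp                 7             4
  focus ratio                    2.07077       0.54558
  occupancy ratio (A/B):   4.31804
  lifetime ratio (A/B):    1.25615
  max-length ratio (A/B):  1.75
  verdict: focused more TSS-focused than flat
```

Reading it: base pairs within ±10 bp of the focused design's TSS are open
(≥ 1 Å) about 3.4 % of the time versus 0.8 % for the flat design, its
bubbles last ~25 % longer on average, it forms openings up to 7 bp wide
there, and its activity is concentrated at the TSS (focus ratio ≈ 2.1
versus a background-like ≈ 0.5), so the categorical verdict —
more-TSS-focused — goes to the AT-block design. At this short test scale
the lifetime half of that verdict is noisy (see `docs/methods.md`); the
contrast strengthens steadily with longer production runs.

The same chain is available from the shell:

```
dnabreathe synth sequence --design focused --out focused.fa
dnabreathe all --fasta pair.fa --out results/ --seed 1
dnabreathe qpcr --ct ct.csv --out qpcr/
```

For qPCR tables, `ddct_fold_change` implements the comparative-CT method
(fold = 2^(−ΔΔCt), normalized to a reference gene, TBP by default) and
`classify_regulation` applies the strict two-fold rule (fold > 2 up,
fold < 0.5 down, else unchanged).

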