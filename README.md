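# memdiff

Quantitative analysis of membrane microdomains in supported lipid bilayers
(SLBs), from two complementary observables:

* **Single-particle tracking (SPT)** — lipid probes diffusing among
  impermeable microdomains show *anomalous* diffusion: the lag-time
  dependent diffusion coefficient D(τ) falls with τ. The inflection points
  of the D–log τ curve, converted to diffusion lengths L = √(4Dτ), measure
  the size of the fluid regions between domains.
* **AFM topography** — the same microdomains appear as ~1.4 nm-deep
  circular depressions; flattening, segmentation and morphometry yield
  their depth, diameter, area fraction and number density, plus a geometric
  estimate of the domain-free region size.

Because raw data for such systems is rarely deposited, the package includes
first-class synthetic generators — an obstructed-diffusion Monte Carlo
simulator, a single-molecule movie renderer, and an AFM topography
synthesizer — so every analysis stage is verifiable against known ground
truth. Who it is for: membrane biophysicists running SPT/MSD or AFM domain
analyses who want a tested, scriptable, reproducible pipeline.

## The analysis in brief

For a trajectory r(iΔt), i = 0..N−1, the mean square displacement at lag
τ = nΔt is the overlapping-window average

    MSD(nΔt) = (1/(N−n)) Σᵢ |r((i+n)Δt) − r(iΔt)|²,

pooled over trajectories with pair-count weights (each trajectory j
contributes N_j − n pairs). The lag-dependent diffusion coefficient is the
through-origin fit of ⟨MSD⟩ = 4D(τ)τ over lags 1..n. Descending and flat
segments of D versus log₁₀τ are fitted with straight lines (manually
chosen ranges or an automatic piecewise-linear breakpoint search); each
inflection (τ, D) gives a diffusion length L = √(4Dτ) — the size of the
region a probe explores before the obstruction at that scale bites.

## Worked example

`examples/obstructed_diffusion.py` simulates probes (D_free = 0.7 µm²/s,
500 fps) in a periodic box with 101 nm impermeable disks at 24% area
fraction — the domain geometry measured by AFM — and runs the full MSD →
D(τ) → inflection chain:

```
obstacles          : 748 disks, fraction 0.240
free-region scale  : 180 nm (equivalent-free-circle geometry)
D at 2 ms          : 0.611 um^2/s (input D_free = 0.7)
D at 300 ms        : 0.525 um^2/s
P1                 : tau = 10.8 ms, D = 0.57 um^2/s, L1 = 157 nm
P2                 : tau = 89.1 ms, D = 0.54 um^2/s, L2 = 440 nm
```

D(τ) falls with lag time — the signature of obstructed diffusion — and the
first inflection's diffusion length (157 nm) recovers the field's geometric
free-region scale (180 nm) from trajectories alone. The second inflection
reflects the larger open corridors a random obstacle packing contains.

Other examples (each runs in seconds to ~1 min and prints what the numbers
mean): `free_diffusion.py` (flat D(τ) at the input value),
`render_and_track.py` (movie rendering and ≥95%-recall re-tracking),
`afm_morphometry.py` (9-image-style domain statistics and free-size
conventions), `inflection_lengths.py` (closed-form L values 234 nm and
452 nm at the reference inflection coordinates, plus manual vs automatic
breakpoint detection).

A thin CLI wraps the same library for shell use:

```
memdiff simulate-spt --out traj.csv --seed 1 --obstacle-fraction 0.24
memdiff msd traj.csv --out study --frame-interval 0.002
memdiff inflect study_dcurve.csv --out inflections.json --single
memdiff simulate-afm --out topo.tif --seed 1
memdiff afm-stats topo.tif --out stats.json
memdiff run study.yaml          # full configuration-driven study
```

Exit codes: 0 ok, 1 configuration error, 2 runtime failure.

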