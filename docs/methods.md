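# Methods

## Scope and model

`alphacell` estimates subcellular absorbed dose and clustered DNA damage
per radioactive decay for four targeted-alpha-therapy radionuclides in a
simplified spherical cell. It is a fast surrogate for condensed-history
Monte-Carlo transport: alphas dominate the nucleus dose at these
geometries, and alphas of 4–9 MeV in water scatter and straggle so little
over ≤ 30 μm that straight-track continuous-slowing-down (CSDA) transport
reproduces condensed-history nucleus S-values at the few-percent level.
Temporal effects (uptake, half-life weighting, repair) are out of scope:
every chain member decays instantly at the parent's position, which is the
standard convention for per-decay S-values.

## Geometry and sources

Two concentric spheres of unit-density water — cell r = 10 μm, nucleus
r = 5 μm — centred in a 30 μm cube; particles reaching the cube wall
terminate. Four source compartments, all sampled uniform-in-volume
(radius by inverse-CDF ∝ r³): membrane shell [10, 10.01] μm, cytoplasm
[5, 10] μm, nucleus wall [5, 5.01] μm, nucleus volume [0, 5] μm.

The nucleus-wall shell sits just *outside* the nuclear boundary: a carrier
docked at the envelope has not internalised. The alternative (inside)
reading is available via `wall_inside=True`. Emission directions are
isotropic — normalised standard-normal triples, which are exactly uniform
on the sphere and vectorise well.

## Decay data

Packaged chains (`data/decay_chains.yaml`) are transcribed from standard
evaluated nuclear data (ENSDF / ICRP-107): alpha line energies and
branching ratios, mean beta energies, principal gammas. Minor alpha lines
(< ~7 % of a nuclide's alpha intensity) are folded into the listed lines
with weights renormalised; this moves chain-averaged alpha energy by well
under 1 %. Validation at load enforces: branch probabilities sum to 1
(±10⁻⁹), all daughters resolve, the daughter graph is acyclic, alpha lines
lie in 4–10 MeV, and `stable` ⇔ no branches.

Chain structure gives exactly 4 alphas per parent decay for ²²⁵Ac and
²²³Ra and exactly 1 for ²¹²Pb and ²¹¹At along *every* branch path — the
mechanism behind the ~4:1 dose-per-decay ordering between the two pairs.
The ratio is not exactly 4 because the chains' alpha energies (hence LET)
differ; enumeration plus the stopping-power table puts it at ~3.9–4.4
depending on pairing.

Long-lived intermediates (²⁰⁷Bi, 31.5 y, in the ²¹¹At chain) are kept by
default — their MeV-scale gammas and conversion electrons escape the world
either way — and can be truncated with `max_half_life`.

Beta spectra are replaced by a single exponential draw with the tabulated
mean energy. This is deliberately crude: electrons above ~6 keV (CSDA
range > 1 μm) are dropped as escaping anyway, so the only role of the
surrogate is to decide, rarely, that a very soft beta deposits locally.
Atomic relaxation (Auger cascades) is not modelled line-by-line; its
omission is visible as a slightly lower total (not alpha) nucleus dose for
internal sources.

## Alpha transport

Electronic stopping powers for alphas in liquid water are packaged on a
31-node grid, 0.1–10 MeV (`data/alpha_stopping_water.tsv`). Above 2 MeV
the values follow Bethe theory (I = 75 eV, Z/A = 0.5551), which matches
the ICRU-49/ASTAR evaluation to ~1–2 % in this range; below 2 MeV the
curve joins the empirical Bragg-peak shape (~226 keV/μm near 0.7 MeV).
Anchors reproduced: ≈ 88 keV/μm at 5.3 MeV; CSDA ranges ≈ 39 μm
(5.3 MeV) and ≈ 41 μm (5.5 MeV). All packaged chains keep alphas above
~2.5 MeV inside the world, so sub-2-MeV accuracy does not influence
nucleus doses.

The table is densified onto a 2048-point log grid; cumulative range
R(E) = ∫dE′/S(E′) is integrated by trapezoid and inverted by monotone
interpolation, giving an energy→range→energy round trip better than 0.1 %.
Residual energy after a path ℓ is E′ = R⁻¹(R(E₀) − ℓ); deposits are
E₀ − E′ per region segment along the ray, with exact per-track energy
conservation. Below the first grid node the remaining energy deposits
locally. No lateral scattering, no straggling: the variance across repeats
comes from decay and geometry sampling, which dominates at 100 sources per
repeat.

Light particles follow a policy rather than transport: electrons with
CSDA range (packaged ESTAR-anchor table) below a 1 μm cut deposit locally
in the containing region, longer electrons and all gammas escape, and
alpha recoils (~100 keV, sub-μm range) deposit at the decay point. A
`recoil_policy="drop"` switch imitates transport codes whose track-
structure physics cannot ionise with heavy daughter ions; it is off by
default. With the default policy the alpha share of nucleus dose is 100 %
for external sources (local deposits stay outside the nucleus) and
~60–70 % for internal sources (recoils contribute the rest) — matching the
qualitative split reported for condensed-history simulations of this
geometry.

## Hits

A particle scores one "hit" if it traverses the nucleus outer surface at
least once (unique-particle counting, not crossing counting — an
alternative convention would count entry and exit separately). For alphas
the traversal test uses the CSDA range against the segment geometry;
escaping electrons/gammas are counted by ray geometry. Locally-deposited
particles never cross.

## Damage scoring

Nucleus chord deposits are discretised into point ionization events:
count ~ Poisson(E/W̄) with W̄ = 37.5 eV, positions uniform along the chord
with isotropic Gaussian jitter σ_r = 3 nm, event energies exponential and
rescaled so their sum equals the deposit exactly. W̄ deliberately equals
the damage-ramp plateau so one parameter controls accepted-break density;
σ_r is a stand-in for the sub-ε delta-electron penumbra, and DSB yields
are sensitive to it — both are configurable and recorded in run metadata.

Each event becomes a candidate strand break with probability
p(E)·f_DNA, where p(E) ramps linearly from 0 at 5 eV to 1 at 37.5 eV and
f_DNA = 0.16 is the fraction of nucleus volume occupied by DNA; the two
thinnings commute into one Bernoulli by independence. Breaks get strand
1 or 2 with probability ½ — the event stream carries no strand geometry —
and are clustered per parent decay (never across decays) with DBSCAN,
ε = 3.2 nm strictly (ties at exactly ε do not join; a measure-zero
choice), core threshold 2 so every pair clusters and chains extend by
density reachability. Classification: clusters containing both strands
are DSBs (size 2 → simple, ≥ 3 → complex); single-strand clusters are
tandem SSBs, singletons SSBs — forced by defining a simple DSB as both
strands broken at one site. A `strandless=True` flag scores any cluster
of ≥ 2 as a DSB for sensitivity analysis. Break conservation
(SSBs + Σ DSB-cluster sizes = accepted breaks) holds by construction and
is asserted in tests against a brute-force union-find oracle.

## Statistics and seeding

A run is `n_repeats` independent repeats of `n_sources` parent decays
(defaults 20 × 100, the study design); every quantity is reported as
mean ± SD over repeats. Repeat r uses the child generator
`SeedSequence([master_seed, r])`, so any single repeat can be re-run in
isolation. Transport is deterministic given a track; all randomness flows
from the per-repeat generator.

`scripts/acceptance.py` reports the cytoplasm and nucleus-volume ²¹¹At
alpha S-values from 2000 sources × 25 repeats — the same estimand as the
20 × 100 design with Monte-Carlo standard error reduced from ~10 % to
~2 % — and the membrane alpha-dose fraction at 100 × 20 per radionuclide.

## Known limitations

* Condensed-history and track-structure electron physics are not
  emulated; published results obtained with track-structure physics in
  the nucleus (higher electron dose, heavy-ion gaps) are outside what a
  CSDA surrogate can reproduce.
* For *external* sources the model tracks published condensed-history
  values from independent work on the identical geometry to ~5 %, but
  sits ~10–17 % above one published full-decay condensed-history dataset
  for the same configuration; straight-ray solid-angle arithmetic
  (0.067 × mean chord × LET) supports the higher value, and the residual
  disagreement between published datasets is of the same order.
* The ionization-event surrogate reproduces densities, not track
  structure: real alpha tracks have correlated ionisation clusters and a
  radial dose profile, so absolute SSB/DSB yields should be read as
  parameter-conditional (W̄, σ_r) rather than predictive; orderings
  across radionuclides and compartments are the robust output.
* Single cell only — no cross-dose between neighbouring cells; spherical
  geometry only.
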