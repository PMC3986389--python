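# Model and methods

`restensim` simulates the wound-healing response of an atherosclerotic
coronary artery to balloon angioplasty with bare-metal stent deployment, on
a two-dimensional cross-section of the treated vessel. The simulation
starts immediately after the procedure and runs until the lumen diameter
stabilizes; its outputs are the final minimum lumen diameter, the time to
stabilization, the percent change in lumen area, and local/serum
concentrations of the two signalling species.

## Lattice, units, and time

The cross-section lives on a 150x150 patch lattice (22,500 patches), one
patch = 0.05 mm, vessel axis at the grid centre. One time step = 6 hours
(4 steps per simulated day). An agent's *local environment* is its patch
plus the 8 adjacent patches; all concentration-dependent rules read that
9-patch window.

The initial anatomy is a set of concentric annuli: open lumen (radius =
half the post-procedural lumen diameter); an intima (innermost 10 % of the
wall, at least one patch) carrying a closed endothelial monolayer and a
sparse SMC population (1 cell per 3 patches); a media (next 60 %) and
adventitia (remainder) filled with 5 SMCs per patch. The wall thickness
defaults to the lumen radius (the typical 1:1 radius-to-wall ratio).
Stent struts (default 20 per stent, 0.1 mm) are evenly spaced squares
pressed into the wall flush with the lumen boundary; a second, overlapping
stent adds a radially adjacent interior ring, aligned with or staggered
between the exterior struts. A plaque pocket (violet, immobile, inert)
sits between intima and media in the bottom-left quadrant; repositioning
it along the circumference does not change outcomes (tested). The
procedure leaves the full endothelial ring flagged as (superficially)
injured and every strut face as a deep injury.

## Behavioural rules

* **Platelets.** A circulating pool of latent platelets (150, replenished
  a few per step by the blood flow) random-walks the lumen. Contact with
  an injury, or with a wound-anchored activated platelet, activates them;
  activated platelets stop moving and aggregate into a thrombus. Lifespan
  5-10 days, drawn uniformly.
* **TGF-beta** (anti-inflammatory). Released by activated platelets and by
  SMCs/ECs on or next to unhealed injuries and monolayer gaps, at the
  nominal rate 0.02 pg/10 h/cell = one 0.012 pg quantum per cell per 6 h
  step, realised as a Bernoulli emission whose probability is
  `release_fraction x injury factor x hoop-stress factor x injury
  severity`. Quanta random-walk one patch per step (tissue and the
  lumen-adjacent boundary only) and decay after 60 h.
* **Leukocytes.** While intimal TGF-beta exceeds the femtomolar-scale
  detection threshold (1 local quantum), monocytes and neutrophils enter
  the lumen (1.2 of each per step) and chemotax toward the nearest wound
  at 1 um/min (7.2 patches per step, 80 % directed). Neutrophils touching
  the thrombus attach and stop. Monocytes reaching wall tissue mature
  into macrophages, which take up residence at the nearest strut (foreign
  body response). Lifespans: monocyte 3 d, neutrophil 5 d, macrophage 45 d.
* **TNF-alpha** (pro-inflammatory). Released by monocytes, neutrophils and
  macrophages — the same nominal rate for all three kinds — wherever local
  TGF-beta is present.
* **SMCs.** Where local TGF-beta >= 3 ng/ml, each SMC divides with
  probability 2^(1/5) - 1 = 0.1487 per step (population doubling every
  30 h); SMCs on injured patches produce two daughters per division.
  Where local TNF-alpha >= 4 ng/ml, SMCs die, hard-capped at 15 % of the
  patch population per exposure step. Proliferating medial SMCs migrate
  lumen-ward at 20 um/h (2.4 patches per step) and become intimal on
  arrival; adventitial SMCs never migrate. A patch holds at most 15 SMCs;
  surplus flows to the least-occupied allowed neighbour with a strong
  lumen-ward preference (a biased sandpile), which also lets tissue seal
  around strut faces.
* **ECs.** The endothelial lining always occupies the lumen-facing
  boundary of the tissue ("adjacent and interior to the forward-most
  SMCs") and is re-seated every step as the frontier advances. Gaps are
  re-covered by sliding/respawn with probability 0.5 per step; ECs die
  under TNF-alpha (15 % cap) and shed spontaneously (monolayer turnover 0.08/step), which keeps a small standing density of
  transient micro-gaps on the regenerating lining. EC proliferation only
  tracks the boundary; it never thickens the neointima.

## Concentration measurement

Local concentration on a patch = (quanta in the 9-patch window) x
0.012 pg / (C x n x a^2), with C = 16/15 mm chosen so one local quantum is
exactly 0.5 ng/ml — the 3 ng/ml proliferation and 4 ng/ml apoptosis
sensitivities are then 6 and 8 window quanta. Edge windows use their
truncated area. The serum concentration (whole-grid mass over the
whole-section reference volume) is a physiological checkpoint only; runs
warn if it leaves [0, 10] ng/ml, and in practice it stays far below.

Two regulatory mechanisms bound the fields without touching the
threshold-crossing dynamics that drive growth: release autoregulation
(secretion pauses where the local level already exceeds 3 ng/ml TGF-beta /
6 ng/ml TNF-alpha) and receptor-mediated clearance (tissue consumes
quanta in excess of 4.3 / 7.5 ng/ml saturation levels, scaled up by the
injury-severity factor). Mass bookkeeping is exact: emitted = in-field +
decayed + consumed, every step.

## Stress modulation and the stopping rule

The thin-wall hoop stress ratio sigma ~ r/t (live minimum lumen radius
over the fixed initial wall thickness, normalised to 1 at the default 1:1
geometry) multiplies the TGF-beta emission probability, and below a
cutoff (`hoop_gate` = 0.70 x injury severity) stretch-driven release stops
entirely — the mechanotransduction stimulus is gone. Because the gate is
expressed in the radius ratio, it produces the near-scale-invariant final
to initial diameter ratio (~0.71-0.73) observed across vessel sizes.

Injuries heal three ways: the denuded ring by sustained endothelial cover
(2 days); any injury by burial under >3 patches of neointima; and a
chronic-resolution backstop at 96 days (x strut-site burden for
multi-stent runs). Because release is injury-driven, a run's TGF-beta
release ends either when the stress gate closes (deeper outcomes, past
the 50 % area-loss restenosis point) or when its injuries resolve first
(shallower outcomes). The mixture of the two routes produces the
clinically realistic heterogeneity in which roughly half of runs do not
reach restenosis.

Stabilization is declared after 4 consecutive steps with zero TGF-beta
emission; the stabilization day is the day of the last emission. The run
then continues 60 more simulated days to confirm the minimum diameter is
static (one-patch tolerance; drift restarts the window); 400 simulated
days is a hard cap, and full occlusion terminates a run early with a
0 mm diameter. The reported final diameter is the median of the
confirmation window, which removes the one-patch flicker of the boundary
scan. Replicate experiments run 10 seeds (base seed + index) and report
mean +/- SD.

## Diameter measurement

The lumen boundary is read from endothelial positions (worst-case,
clinically conservative convention). 180 evenly spaced rays through the
fixed vessel axis are scanned; each diameter is the sum of the innermost
endothelial radii in the two opposed angular sectors plus one patch (the
cells' luminal faces); the minimum over rays is the minimum lumen
diameter. Doubling the ray count moves results by well under one patch
(tested). Percent area change is 100 x (1 - (d/d0)^2); restenosis is
strictly more than 50 % area loss.

## Calibration

The literature-derived constants (release rate, sensitivities, migration
speeds, doubling time, apoptosis cap, lifespans, strut defaults) are taken
as given. The knobs the physiology does not pin down — emission fraction
and surface-exposure cap, injury release factor, hoop-stress cutoff,
autoregulation and clearance levels, EC turnover and re-seating rates,
leukocyte recruitment rate, injury healing depths/times — were tuned once
against the three serial-imaging validation scenarios (final diameters
2.13/2.34/1.75 mm, stabilization 89/82/93 days, peak local TGF-beta ~6
and TNF-alpha ~9 ng/ml, ~40 % of runs below the restenosis point) and then
frozen as the package defaults. They are ordinary config fields, so the
sensitivity scanner can perturb any of them.

## Numerical and design choices

* Sub-step order within a tick: platelets -> TGF-beta release ->
  recruitment -> leukocyte movement -> TNF-alpha release -> diffusion,
  decay and clearance -> SMC dynamics -> EC re-seating -> metrics.
* One `numpy` Generator per run, seeded by (base seed + replicate index);
  equal seeds reproduce runs bit for bit.
* Dense populations (SMC, EC) are per-patch count grids; platelets,
  leukocytes and cytokine quanta are particle arrays.
* The lumen is the flood-filled free region containing the axis, after a
  morphological closing (border-filled) that seals crevices narrower than
  the endothelial bridging scale (~2 patches).
* Degenerate cases: a patch on the axis has no centre-ward direction and
  spills randomly; a fully wedged patch (struts/plaque on all sides)
  retains its surplus; an axis overgrown by tissue sets the occlusion
  flag (diameter 0, 100 % area loss).

## What the model does and does not capture

Outcome statistics (mean final diameters, stabilization times, cytokine
bounds, restenosis fraction) are reproduced; visual lobed growth around
struts emerges naturally. The model ignores extracellular-matrix
deposition, vessel remodeling, plaque rupture and acute thrombosis
therapy, drug elution, 3-D stent-cell geometry, and treats TGF-beta as a
single-modality cytokine. The replicate SD of the final diameter (~0.05
mm) refers to the converged mixture of growth routes; single extreme runs
(near-total occlusion) are possible in principle but are not produced by
the frozen default calibration. Stabilization-time spread is a few days,
driven by the race between injury resolution and the stress gate rather
than by follow-up-window censoring as in imaging studies.
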