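# Methods

This note documents the models inside `bdpc-imrt`: what is simulated,
which parameters matter, and where the sandbox deliberately departs
from clinical reality.

## The synthetic thorax phantom

A phantom is a voxel grid of mass density plus boolean structure masks.
Default grid: 64 × 64 × 32 voxels at 4 mm (a planar mode with nz = 1 is
used throughout the fast tests); the resolution is configurable, and a
finer grid only sharpens DVH estimates.

Geometry is parametric, not anatomical: the body is an extruded
ellipse; lungs are two ellipsoids (density drawn once per phantom from
0.20–0.35 g/cm³, soft tissue 1.0 g/cm³); spinal cord, esophagus and
heart are tubes/ellipsoids placed per laterality; several concentric
ring structures surround the target for conformity shaping. The
planning target volume (PTV) is a sphere whose volume is drawn from
205–409 cm³ (the range of the emulated 13-patient cohort; the draw is
taken 3% inside the window so voxelization cannot push it out). Its
center sits at the medial edge of the ipsilateral lung so the target
*always* straddles the lung/mediastinum density boundary — the
precondition for an optimization-convergence error — with a soft-tissue
tumor core (45% of the PTV radius) in the middle. Large targets are
shifted laterally so they never touch the contralateral lung.

What the phantom does **not** model: real CT texture and HU-to-density
calibration, respiratory motion, anatomical lung shapes, bone. Results
on these phantoms therefore demonstrate the *mechanism* of the
compensation method, not absolute clinical dose values.

## Dose engines

Both engines are pencil-beam models on coplanar parallel beams (six
gantry angles per laterality: 330/20/70/120/165/210° left-sided,
195/240/290/340/30/150° right-sided) discretized into 8 mm beamlets
covering the PTV projection plus a 10 mm margin. A beamlet deposits

    D(v) = exp(−μ · depth(v)) · f(v) · w² / (2πσ(v)²) · exp(−r²/2σ(v)²)

(planar mode uses the 1-D lateral kernel). The engines differ in the
three ingredients:

| ingredient | simplified (optimizer) | accurate (final dose) |
| --- | --- | --- |
| depth | geometric path through the body (unit density) | radiological depth ∫ρ dl |
| lateral σ | σ₀ | σ₀/ρ(v), clipped to [0.5σ₀, 1.5σ₀] |
| deposition f | 1 | ρ(v)^γ |

Defaults: μ = 0.0025 mm⁻¹, σ₀ = 4 mm, γ = 0.08, kernel cutoff 3.5σ,
matrix entries below 10⁻⁴ of the beamlet maximum dropped (this floor
bounds the DVH discretization error), ray-sampling step 2 mm with
trilinear interpolation (a fixed-step resampling rather than exact
voxel traversal; at 2 mm the line-integral error is well below the 2%
tolerance of the closed-form attenuation test).

The deposition factor ρ^γ is a lumped model of lateral electronic
disequilibrium: in low-density tissue the secondary-electron range
grows and local dose falls. It is needed because the other two accurate
-engine corrections *oppose* each other in the mean over the
lung-density target: radiological depth is shorter than geometric depth
behind lung (raising dose), while kernel widening only drains dose near
field edges. The triplet (μ, σ-clip, γ) was calibrated once so that

* the accurate engine is strictly colder than the simplified engine
  over PTV_lung at equal fluence (the documented direction of the
  error), stable across seeds;
* a conventional plan degrades to HI ≈ 0.2 on the planar phantoms —
  a pronounced but realistic error, leaving room for partial (STO) and
  near-complete (BDPC) compensation.

On a uniform unit-density phantom the engines coincide to < 1%
(interpolation noise only): the error vanishes without heterogeneity,
which the no-compensation null test exploits.

## Fluence optimization

Projected gradient descent with Armijo backtracking on the weighted sum
of one-sided quadratic penalties; dose-volume (DVH) objectives penalize
only the violating voxels closest to the threshold, re-selected every
iteration (the classic construction; a known source of local minima,
accepted because the solver is deterministic and warm-startable). Each
term is normalized by its structure's voxel count so weights compare
across structures. Convergence: relative penalty decrease < 10⁻⁵ over a
10-iteration patience window, cap 500 iterations (the BDPC
re-optimization uses its own cap, default 200 — this outer-iteration
cap is *not* equivalent to a commercial optimizer's "20 maximum
iterations", which counts a different unit of work).

The shipped objective preset encodes the stage III lung constraint
table (cord < 45 Gy, total-lung V20 < 30%, contralateral V5 < 50%,
MLD < 20 Gy, esophagus < 105% prescription) plus a PTV uniformity pair
(minimum 60 / maximum 63 Gy). Target weights (300/200) dominate OAR
weights (2–20) by design — target coverage carries the highest
priority, and in the planar geometry several volumetric OAR objectives
are genuinely unattainable (a single slice through the lungs receives
every beam), so they act as soft pressure rather than hard goals. The
final-dose constraint check reports pass/fail per plan and flags
failures; it never aborts a run.

## Planning strategies

All three strategies optimize on the simplified engine, compute the
final dose on the accurate engine, and normalize the plan so the
prescription (2 Gy × 30 = 60 Gy) covers 90% of the PTV (D90% →
prescription; fluence and both dose grids scale together).

* **CO**: one pass, zero base dose.
* **STO**: every PTV objective is split over PTV_soft / PTV_lung with
  component weights proportional to voxel counts (so a zero boost is
  algebraically identical to CO) and the lung component's dose levels
  raised by `lung_boost_gy` (default 3 Gy, the middle of the 2–4 Gy
  convention). An empty PTV_lung falls back to CO with a warning.
* **BDPC**: the finished CO plan at half its fractions is the base
  dose plan — since dose is linear in fraction count, halving fractions
  is implemented exactly as 0.5 × the CO final-dose grid. The top dose
  plan starts as a duplicate of the CO fluence and is re-optimized with
  the base dose added and objectives unchanged, so the optimizer shapes
  the *plan sum* (interpreted on the summed grid) toward the full
  prescription: wherever the base is cold the believed sum forces extra
  fluence, wherever it is hot the fluence backs off. Restoring the
  fraction count (15 → 30) doubles the half-course dose, and the plan
  is normalized. Residual inhomogeneity is second order in the local
  engine-discrepancy ratio plus the width of the PTV objective band.

## Monitor-unit proxy

Absolute MU depends on leaf sequencing, which is out of scope (the
fluence map is the deliverable here). The default proxy is the
dynamic-MLC (sliding-window) beam-on-time model: per beam and fluence
row, the sum of positive fluence increments along the leaf-travel axis,
divided by the fraction count; calibration constant 1.0 (relative
units). It is positively homogeneous (doubling fluence doubles MU) and
charges for *modulation*, which is exactly why the compensated plans
cost more MU. A plain fluence-sum proxy is available
(`total_MU(plan, model="fluence_sum")`); it is nearly blind to the
extra modulation because the D90% normalization inflates all methods'
totals by similar amounts. Peripheral dose and beam-on time deltas use
the measured conversion 2.44·10⁻³ cGy/MU (20 cm from isocenter) and a
600 MU/min dose rate.

## Evaluation

Cumulative DVHs with 0.05 Gy bins, exact at bin edges; D_x% by linear
interpolation of the inverse curve with the conservative (leftmost)
convention on flat segments; V_x by linear interpolation between edges.
CI is Paddick's (TV_PIV)²/(TV·PIV) evaluated on the normalized final
dose; HI is ICRU-83 (D2% − D98%)/D50% (scale-invariant, so
normalization leaves it unchanged up to binning); NT V107% is the
absolute normal-tissue volume at ≥ 107% of prescription. Report
rounding follows the usual table conventions (two decimals for CI/HI).

## Cohort statistics

One-way repeated-measures ANOVA (classical SS decomposition, F =
MS_methods/MS_error with df (k−1, (k−1)(n−1))); no sphericity
correction is applied, and reports say so. LSD pairwise comparisons use
the pooled error MS, are gated on the omnibus p < 0.05, and are flagged
at α = 0.05/3 ≈ 0.017 (Bonferroni over the three pairwise tests).
Degenerate tables (zero error variance) are reported with p at the
machine floor and an explicit flag.

## Problem sizes and determinism

The default cohort experiment uses 13 phantoms (the emulated cohort
size); the test suite and examples use 10-seed planar cohorts and a
64 × 64 × 32 grid for single 3-D demonstrations — sizes chosen so a
full plan optimization completes in seconds and a cohort in about a
minute on one core. Every random draw flows from
`numpy.random.default_rng(seed)`; identical configs give bit-identical
phantoms, plans and CSVs (the config hash stamped into artifacts
excludes the output directory).

## Known limitations

* Parallel-beam geometry (no divergence), no build-up region, no
  scatter kernels beyond the single Gaussian; the deposition exponent
  is a phenomenological stand-in for transport physics.
* MLC sequencing, couch/collimator angles and beam-angle optimization
  are out of scope; MU is a relative proxy.
* The planar mode exaggerates lung involvement, so volumetric OAR
  constraints routinely flag there; flags are informational.
* Absolute cohort dose statistics are not comparable to clinical
  tables produced by commercial systems on patient CTs; only the
  directions and orderings of method differences are meaningful.
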