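# Methods

## Model overview and assumptions

The simulator represents one cortical area as a bounded region of the
complex plane (units mm, time in seconds).  It deliberately replaces
biophysics with geometry and event timing:

- **Projection geometry.** Each local map is the projection
  `p = p′ w_cⁿ/|w|ⁿ⁻¹ + p₀` with `w = P − p₀`, where `w_c = w` for
  chirality +1 and `w̄` for chirality −1.  We interpret chirality as
  complex conjugation (a true mirror) rather than a sign prefactor: a sign
  flip is a rotation by π, which can neither produce mirror-image
  neighbouring maps nor reverse pinwheel winding, whereas conjugation
  satisfies the angle-multiplication law
  `arg(p−p₀) = chirality·n·arg(P−p₀) + arg(p′) (mod 2π)` exactly.
- **Limbs.** Azimuths are partitioned half-open: `arg(P−p₀) ∈ [0, π)` is
  limb +1, `[π, 2π)` limb −1, making the two-limb classification exact in
  floating point (with a guard for the `-eps mod 2π = 2π` rounding case).
- **OP and winding.** OP is the orientation of the radial like-to-like
  line, `arg(P−p₀) mod π`; it is identical on the two limbs.  Because any
  continuous function with OP(α)=OP(α+π) must wind by a multiple of 2π
  over a 2π circuit of the *global* azimuth, the observable half-pinwheel
  (total winding π, sign = chirality) lives in the local (cortical) plane,
  where one circuit of the cluster corresponds to a π range of source
  azimuths.  `op_winding` measures winding there.
- **Pulse-pair kinematics.** Implemented exactly as the closed forms in
  the module docstring of `pinwheels.stimulus`: the same-line crossing
  interval is `mL/(V sin θ)` (line traversal at velocity `V sin θ` along
  the segment), *not* an independent plane-wavefront derivation.  One
  consequence, flagged here deliberately: event trains generated at rate
  `KV` per source yield a matched-pair coincidence rate of `KV` at λ = 0,
  which coincides with `ω = ν/ΔS = K′V sin θ` exactly when `m = sin θ`
  (canonically m = 1, θ = π/2).  Oracle-vs-ω rate checks therefore use
  that canonical synchronous family; for all other configurations the
  oracle is checked against the lag λ itself, which is unambiguous.
- **Free energy.** `F = A − C` needs an estimator; we fix zero-lag
  Pearson correlation of spike counts binned at 10 ms, with `C` averaged
  over partners (`Σ_{i≠j} corr/(N−1)`) so that two identical trains give
  A = C = 2, F = 0 and independent trains give F ≈ N exactly as intended.
  Trains come from a seeded common-source surrogate: each bidirectionally
  linked pair shares a Poisson component with fraction
  `min(g_ij, g_ji)/g_max`, which makes pairwise correlation track
  bidirectional gain — the only property the diagnostic uses.

## Learning rule

Per epoch and per mapped pair (consecutive-ring "radial" pairs and
adjacent-line "circumferential" pairs within one limb), the lag λ is
evaluated against every ensemble grating with the relative tolerance
`|λ| ≤ lambda_tolerance · δT` (default 5 %, dimensionless and
scale-free).  A pair synchronous under *any* grating receives one
bidirectional soft-capped gain increment (`g ← g + η(1 − g/g_max)`,
creating the reverse edge if absent); otherwise the majority lead→lag
direction receives one directed increment.  Exactly one update per pair
per epoch keeps gains on a multi-epoch trajectory; per-grating updates
would saturate the cap within ~2 epochs and flatten every learning
trend.  A pair establishes its STO (the angle φ of its source segment to
the radial direction) after 3 consecutive synchronous epochs.

STO interpolation encodes φ ∈ [0, π/2] as `u(φ) = exp(2iφ)` on the upper
unit semicircle, combines with weights `1/(1 + C_range·r²)` and decodes
as `arg(Σ)/2`.  The doubling makes the radial and circumferential
extremes antipodal and keeps any positive combination inside [0, π/2]
with no extra folding; single-source and constant fields are exact fixed
points.  (An encoding with multiplier 4 would identify the two extremes,
`exp(4i·0) = exp(4i·π/2)`, and was rejected for that reason.)

Crossed inhibition at each pinwheel core is a one-shot winner-take-all
between the radial and circumferential groups of established pairs,
comparing **mean gain per pair** (intensive) with seeded log-normal
symmetry breaking (`wta_sigma`, default 1.0) and a configurable prior
(default 0.5).  The intensive comparison matters: the scaffold always
holds more radial than circumferential pairs, and comparing summed gains
would bias every core toward the low-SFP outcome instead of the
near-even split the competition is meant to produce.  Outside the core a
cell follows its circumferential group when it has one (the synergic
periphery) and its radial group otherwise; continuous SFP is
`ν/(⟨|ΔS|⟩·V_ref)` (cycles/mm) with gain-weighted ⟨|ΔS|⟩, and TFP is
`ν/⟨|ΔS|⟩`.

Long-range bridging evaluates the general-case path difference through
the inverse maps, `ΔS = |P₁−p₁| − |P₂−p₂|` with each `P` recovered on the
cell's own limb and map, for every cross-limb/cross-map cell pair, and
creates reciprocal "bridge" edges where some ensemble grating brings
`|λ|` within the relative threshold (threshold 0 admits nothing).

## The response observable

The lag algebra is independent of K (only `mL = |P₁P₂|` enters δT), so
lag selectivity alone cannot produce space-frequency tuning.  The
response of a cell is therefore defined as

    response = Σ_pairs gain · (same-line coincidence rate) ·
               exp(−ln²(KV/ω) / 2σ²),          σ = sigma_rate = 0.2

where the coincidence rate is measured on the event oracle (same-line
matching: the k-th crossing of P₁ against the k-th of P₂, which is offset
by exactly λ) and the log-Gaussian factor expresses the assembly's
preference for being driven at its own synchronous rate ω.  TFP sweeps
use K = 1/separation and the orientation orthogonal to the dominant pair
so the stimulus temporal frequency KV reads directly in ω units; SFP
sweeps at fixed `V_ref` first open the lag gate at the orientation with
`sin θ* = sep·ν/(V_ref·|ΔS|)` and then the resonance factor selects
`K̂ = ω/V_ref`.  Square profiles sum their odd harmonics (amplitudes 1,
1/3, 1/5; truncated at the 5th — higher terms change nothing
qualitative), which is what advantages broadband (high-SFP) cells.
Two-grating cancellation applies the crossed-inhibition rule to the two
drive groups: `combined = (1 − inhibition·conflict)·max(r₁, r₂)` with
conflict = 1 − Jaccard overlap of the resonant pair sets.

## Fixtures: what the generator emulates

Fixtures realise the study conditions at desk scale.  Geometry defaults:
map spacing 1 mm, map radius 0.45·spacing, `p′ = −1/4`, n = 2, 8 radial
half-lines × 3 rings per map (24 local excitatory cells and 24 patch
cells per map, ~50 cells for the single-map fixture), conduction speed
ν = 0.3 mm/ms, like-to-like lines bending circumferentially toward the
periphery by `chirality·0.35·(r/R)²` radians.  The bend is what makes
circumferential-pair geometry ring-dependent, so a stimulus ensemble can
address the innermost and outermost rings without also recruiting the
mid ring.

The grating ensemble is *designed from the scaffold*: one grating per
pair class, oriented orthogonally to the pair segment with speed set by
the zero-lag condition `V = sep·ν/ΔS`, for all radial pairs and for
circumferential pairs of the innermost ring (creating the core conflict)
and the outermost ring (the synergic periphery); any grating that would
also synchronise a mid-ring circumferential pair is pruned.  Because
ΔS ≤ mL, synchrony requires `V sin θ ≥ ν`; stimulus speeds in this model
are therefore of the order of the conduction speed (hundreds to
thousands of mm/s on the sheet) and `V_ref = 10ν` is the SFP readout
speed.  These are conditions of the model's own algebra, not retinal
velocities — there is no retina/LGN stage, no receptive fields, no
noise in the stimulus path, and grating ensembles are resonant by
construction rather than sampled from natural statistics.  Passing tests
therefore show that the mechanism produces the claimed organization
under its stated kinematics, not that it survives realistic input
statistics.

Three named fixtures: `one_map_minimal` (1 map, 52 cells),
`two_map_mirror` (2 maps of opposite chirality with overlapping
projection discs, for bridging), `ensemble_20maps` (5×4 maps, 1040
cells, centre jitter 0.05 mm, for population statistics).  Learning runs
use 10 epochs; the free-energy surrogate uses rate 20 s⁻¹ for 10–20 s at
10 ms bins.  These sizes were chosen so a full three-seed ensemble study
runs in seconds while keeping ≥ 10 epochs of trend and 20 cores for the
bimodality statistics.

## Numerical choices

- Geometric identities are asserted at 1e−9 relative; double-precision
  complex arithmetic throughout.
- `sin θ` below 1e−12 snaps to 0 so the parallel-lines sentinel (infinite
  crossing interval) triggers reliably.
- Inverse maps for n > 2 have n/2 preimages per limb; a `branch` argument
  selects among them (branch 0 = principal).  Round-trip guarantees are
  stated for n = 2; higher n is supported and checked only through the
  forward invariants.
- Coincidence detection is greedy one-to-one two-pointer matching; the
  window is always passed explicitly by callers (learning uses the
  relative λ tolerance).
- Degenerate inputs: the singularity is a fixed point of the forward map
  (limb +1 by convention); OP, STO and the path difference raise at the
  singularity; empty pulse trains contribute autocorrelation 0 and are
  flagged; zero-epoch training returns the connectome unchanged.
- Determinism: every stochastic step consumes a `numpy` Generator seeded
  from the master seed (per-epoch surrogate seeds are derived by a fixed
  affine-mod scheme); CSV/JSON/GraphML artifacts are byte-identical for
  identical (config, seed).

## Known limitations

- The antenatal phase is represented by its end-state geometry; no
  neural-field dynamics, apoptosis, or inhibitory spiking is simulated —
  inhibitory cells exist as labels for the competition rule.
- Ocular dominance, direction preference, OP fractures and inter-areal
  extensions are out of scope.
- The kinematic convention follows the printed traversal form
  (`mL/(V sin θ)`); a plane-wavefront reading would give
  `mL·sin θ/V`.  We implement the former and confine rate-vs-ω claims to
  the self-consistent canonical family (see above).
- `m = |P₁P₂|·K` is treated as a real number at run time; integer m is a
  property of fixture construction, not a constraint of the operations.
- The ranking-invariance of STO interpolation under rescaling of
  `C_range` is a qualitative property that holds along transects between
  sources; it is not a theorem for arbitrary query sets.
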