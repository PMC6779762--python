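# Methods

## Scope and models

`fflcap` quantifies how the decoding section of the MAPK/ERK pathway —
two nested coherent type-I feed-forward loops (FFLs) between cytoplasmic
ppERK and the transcription factor pcFos — transmits information about
stimulus intensity, and how promoter affinity and extrinsic noise shape
that transmission.  Four stochastic reaction networks are simulated:

1. **MAPK/ERK decoding section** — 8 species, 14 reactions.  ppERK_cyt
   is imported to the nucleus (k1 = 15/min), removed by constitutive
   phosphatases (k2 = 50/min) and by the accumulating phosphatase DUSP
   (k3 = 14/min per DUSP); ppERK_nuc activates RSK (k4/k5) and, jointly
   with RSK through a Hill function (half-saturation k6 = 0.13 on the
   ppERK_nuc·pRSK_nuc product, exponent n = 1.1, unit prefactor), drives
   cFos transcription, processing (k7), decay (k8), translation (k9) and
   degradation (k10); ppERK_cyt stabilizes cFos into pcFos (k11 =
   0.11 per molecule per min), reversed at k13 with slow pcFos loss k12.
   DUSP is produced (k = 1/min per ppERK_nuc) and never degraded: it
   accumulates for as long as input is present.  That divergence is part
   of the model; the steady-state solver reports DUSP as divergent and
   gives the asymptotic limits of the remaining species.
2. **Minimal decoder** — proteins B..E in the same nested-FFL wiring,
   all with production k = 20/min and decay g = 0.1/min.  The bilinear
   activations of D and E are normalized by A_N·G_N² (A_N = L(k1−k2) of
   the driving input, G_N = k/g = 200) so every protein shares the
   deterministic steady state SS = A_N·G_N; amplification is removed and
   only the topology remains.
3. **Linear chain** — identical except D reads only C and E only D.
4. **Reporter gene** — a single-copy two-state promoter (activation
   κ_pm·Hill(TF; scale·K_rp, n_g = 2)·P*, κ_pm = 0.1/min, K_rp = 100,
   inactivation γ_pm = 0.2/min) with constitutive transcription
   (κ_m = 14/min), mRNA decay (γ_m = 1/min), translation (κ_p = 20/min)
   and protein loss (γ_p = 0.1/min).  Affinity variants scale K_rp by
   0.1 (H), 1 (N) or 10 (L); affinity is the inverse of K_rp.

Stoichiometry follows the deterministic rate equations: activation
steps with no loss term for the activator in the ODEs are catalytic
reads.  In particular ppERK_cyt is *prescribed*: it evolves only under
the input hazards below, and the import and stabilization reactions read
it without consuming it.  Concentration units map 1:1 to molecule
counts, as in the published stochastic treatment; this leaves cFos-arm
copy numbers small (pcFos peaks near 20 at L = 100), which is why
reporter activation is rare at nominal affinity.

## Input model

The stimulus is the transient
`ppERK_cyt(t) = L[k2(e^(−t/T2)−1) − k1(e^(−t/T1)−1)]`, with three
published shape sets (I1, I2, I3) fit to 0.1/1/10 nM EGF doses and the
scale L swept from 10 to 120 in steps of 10 as the stimulus alphabet.
Stochastically the input is a pair of time-inhomogeneous reactions with
hazards `(k1·L/T1)e^(−t/T1)` (birth) and `(k2·L/T2)e^(−t/T2)` (death) —
the signed parts of the trace's derivative — so the ensemble mean
follows the trace.  Two consequences matter downstream:

* the death hazard is count-independent, so it is clamped to zero at
  zero copies (bias negligible: the trace is positive wherever the
  hazard is appreciable), and `k1 > k2` alone does not keep the early
  transient non-negative — `InputSpec` additionally requires
  `k1/T1 ≥ k2/T2`, which all standard sets satisfy;
* both hazards vanish as t grows, so the input *freezes* with variance
  ≈ L(k1+k2) (sum of event counts), i.e. a late-time CV of
  `sqrt((k1+k2)/L)/(k1−k2)` — about 0.5 for I2 at L = 100, and ordered
  I1 > I2 > I3 across the input shapes.  This frozen randomness is the
  dominant noise source of the minimal decoder and drives most of the
  nonlinear effects discussed below.

## Stochastic engine

Exact simulation with time-varying hazards uses thinning: the waiting
time is proposed from the total propensity frozen at the current
(state, time), which bounds the true rate over the waiting interval
because the input hazards only decay and everything else is constant
between events; proposals are accepted with probability true/bound and
the reaction is chosen proportionally to the true rates at the accepted
time.  Input hazards below 1e-12 events/min are treated as zero
(expected events dropped over 200 min < 2e-10).  Extrinsic-noise updates
and sample times are handled as interval boundaries, so every segment
satisfies the bound.

The inner loop is numba-compiled with the total static propensity
maintained incrementally (per-reaction affected-reaction lists) and an
inlined xoshiro256++ generator seeded per realization from a
`SeedSequence` spawn of the master seed; ensembles are bit-reproducible
from (seed, condition) and run at roughly 10–20 million events per
second on one core.  A realization of the MAPK network over 200 min
involves a few hundred thousand reaction events; the minimal decoder at
L = 100 about a million.

Extrinsic noise follows the published recipe: one mass-action rate
(default k11) becomes `nominal · exp(ε·Z)`, Z standard normal — a
lognormal with median equal to the nominal value — redrawn at absolute
times 0, P_ext, 2P_ext, … and held in between, independently per
realization.  ε = 0 still runs the update process (every draw equals
the nominal exactly), so zero-intensity controls are independent
replicates rather than replays.

## Information readouts

At each sample minute the response alphabet of a species is built by
splitting the pooled min–max range over all L levels into 64 equal-width
bins (shared support is required for a well-defined channel; 64 bins
keep the three-gene joint summation tractable); per-level normalized
histograms form P(R|S).  Channel capacity is computed by Blahut–Arimoto
from a uniform start, stopping when the standard upper/lower bound gap
(max-divergence vs current mutual information) is below 1e-6 bits.
Multivariate mutual information of a gene set assumes conditional
independence of the reporters given the stimulus — P(r1..rn|s) =
ΠP(ri|s) — and by default evaluates the factorized joint channel at its
own capacity-achieving input distribution (the ceiling of jointly
extractable information); all-zero joint cells are dropped before the
maximization.  No small-sample bias correction is applied, matching the
published procedure; consequences are noted below.  The coefficient of
variation is SD/mean across realizations at a fixed time (NaN at zero
mean).

Trend conclusions are tested, not eyeballed: one-sided bootstrap over
realizations (200 resamples, paired whenever both readouts come from the
same ensembles), at the 0.05 level.

## Study profiles and problem sizes

The published protocol is 1000 realizations per L level, 200 min,
per-minute sampling, 12 L levels (`ExperimentConfig.full`).  The default
working profile (`ExperimentConfig.desk`) uses 200 realizations and 6
levels {10,30,…,110}; it reproduces every ordering that the full profile
supports while keeping the whole five-experiment suite under ~10 CPU
minutes.  The extrinsic-noise grids are not printed in the source
material; the defaults here are ε ∈ {0, 0.5, 1} and P_ext ∈ {1, 200}
min (the extremes of fast and frozen noise), all config-overridable.

## What the generator does and does not emulate

The synthetic ensembles carry intrinsic (event-level) noise and, when
requested, one controlled extrinsic parameter process.  They do not
model the upstream coding section (growth factor → ppERK), cell-cycle or
volume effects, transcriptional bursting beyond the two-state promoter,
or correlated extrinsic noise across parameters.  Passing tests
therefore validate the decoding-section model as printed, not MAPK
biology at large.

## Findings that differ from the source narrative

Faithful simulation of the model as printed produces three deviations,
all traceable to one mechanism — the input's frozen variance passing
through the bilinear FFL steps (E[BC] > E[B]E[C]):

* the stochastic means of D and E sit ~25% and ~75% above the shared
  deterministic steady state (B, C and the whole linear chain match it
  exactly), so "all proteins reach SS" holds for the mean-field model
  only;
* the late-time capacity is not equal across B..E — D and E carry more
  noise and measurably less stimulus information;
* the FFL and linear-chain capacities differ clearly (the claim that
  they do not presumes the equality above).

Separately, nuclear ppERK relaxes in 1/k2 = 0.02 min and is therefore a
nearly instantaneous, low-noise readout of the input: its capacity
spikes in the first sampled minute above everything downstream.  The
downstream ordering pcFos > cFos > ppERK_nuc holds from ~20 min onward.
And in the extrinsic-noise study the reporter's true stimulus
information is of order 0.01 bits; at 200 realizations the
occupancy-dependent histogram bias exceeds the effect of ε, inverting
the expected decrease (the direction recovers at larger ensemble
sizes).  These observations are measured by the test suite and reported
as such; the corresponding assertions are deliberately left failing
rather than weakened.

## Numerical choices and degenerate inputs

* ODE validation uses LSODA at rtol 1e-8 / atol 1e-10 (oracle-grade at
  this dimension); the steady-state solver seeds a Newton/hybr root from
  a long integration, reports never-degraded species as divergent, and
  clamps them at 1e12 to extract the limits of the coupled species.
* A degenerate pooled response range (all observations equal) yields a
  valid single-bin channel with zero capacity — this is how t = 0 and
  silent reporters are handled.
* Blahut–Arimoto input updates are computed in the log domain; 0·log 0
  terms are 0 throughout.
* Promoter copy conservation (P* + P_m = 1) is enforced by construction
  and asserted in tests on every sampled state.
* Tie-break on equal-width binning: `np.histogram` right-open bins with
  the final bin closed.

## Limitations

Capacity estimates at 200 realizations carry an upward bias of order
0.05 bits that grows with occupied support; comparisons across
conditions with similar support (the ordering tests) are robust to it,
absolute values are not.  The MMI independence assumption ignores the
real within-cell correlation of reporters sharing a pathway, as in the
source procedure.  Exact SSA limits practical ensemble sizes; no
tau-leaping or hybrid acceleration is provided.
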