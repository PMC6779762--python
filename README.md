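# fflcap — information transmission through feed-forward-loop decoding

Cells read the *dynamics* of signalling intermediates, not just their
levels.  In the MAPK/ERK pathway, a decoding section built from two
nested coherent type-I feed-forward loops (FFLs) converts the transient
of doubly phosphorylated ERK (ppERK) into a pcFos transcription-factor
response, which downstream promoters then read with affinity-dependent
sensitivity.  `fflcap` is an analysis code base for asking, with
Shannon's tools, how much stimulus information survives that decoding:

* **Channel capacity** of a molecular readout R for a stimulus S taking
  one of a set of intensities L:
  `CC = max_{P(S)} I(R;S)`, with `I(R;S) = H(R) − H(R|S)`, computed by
  the Blahut–Arimoto algorithm on per-minute histogram channels
  P(R = r_i | S = s_j) estimated from trajectory ensembles.
* **Multivariate mutual information** of a set of reporter genes,
  `I(R_1..R_n; S)` with `P(r_1..r_n|s) = Π P(r_i|s)` (conditional
  independence), the non-redundant information of the ensemble.
* **Coefficient of variation** SD/mean across realizations, the noise
  readout.

The trajectory ensembles come from an exact stochastic simulation
(thinning for the time-decaying input hazards, numba-compiled core) of
four models: the MAPK/ERK decoding section, a minimal four-protein
nested-FFL decoder with normalized steady state, its linear-chain
control, and single-copy two-state promoter reporter genes, optionally
under a controlled extrinsic noise process (piecewise-constant lognormal
fluctuation of the pcFos phosphorylation rate k11).  Model equations,
rates, and all numerical choices are documented in
[docs/methods.md](docs/methods.md).

Intended users: computational/systems biologists studying information
transmission in signalling, and anyone needing a tested, reproducible
SSA + channel-capacity pipeline for small reaction networks with
prescribed time-varying inputs.

## Layout

```
src/fflcap/       library: inputs, networks, ssa, ode, infotheory,
                  fixtures, experiments
analysis/         numbered study drivers (01 engine validation ...
                  06 extrinsic noise); each writes tidy CSVs under
                  results/ and prints its findings
scripts/          acceptance.py — recompute headline numbers as JSON
tests/            pytest suite incl. the acceptance/trend suite
```

## Worked example

Capacity along the decoding section, with one reporter gene coupled to
the pathway output (Prt_w, reads pcFos) and one to the pathway entry
(Prt_wo, reads ppERK_nuc):

```bash
python analysis/02_mapk_capacity.py --seed 1 --profile desk
```

prints

```
profile desk: 200 realizations x 6 stimulus levels
  ppERK_nuc  peak CC 0.638 bits, late CC 0.048 bits
  cFos       peak CC 0.300 bits, late CC 0.124 bits
  pcFos      peak CC 0.598 bits, late CC 0.351 bits
  Prt_w:P    peak CC 0.077 bits, late CC 0.026 bits
  Prt_wo:P   peak CC 0.000 bits, late CC 0.000 bits
reporter amplification: max mean Prt_w 39 vs Prt_wo 0.0 (>10x (Prt_wo
essentially silent)) — the pathway-coupled gene is both more expressed
and more informative
```

Reading this: each capacity is measured against a 6-letter stimulus
alphabet (L = 10..110), so the ceiling is log2(6) ≈ 2.58 bits.  The
pathway output pcFos retains far more stimulus information at late
times (0.35 bits) than nuclear ppERK (0.05 bits), and the reporter
coupled to it dominates the directly-driven reporter in both expression
(Prt_wo fires in under 1% of realizations) and capacity — the FFL
amplifies while adding noise, and the amplification wins.  Nuclear
ppERK's own capacity peaks in the very first minute (it is an
instantaneous readout of the input, relaxing in 1/k2 = 0.02 min) and
decays as DUSP feedback shuts it down.

The other drivers follow the same pattern: `03` the minimal decoder
across the three input shapes (late-time capacity ordering
I3 > I2 > I1 and CV growth along B→E), `04` FFL vs linear chain,
`05` promoter-affinity triplets and their joint information,
`06` the extrinsic-noise surface.  `--profile full` switches any of
them to the published protocol (1000 realizations, 12 levels).

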