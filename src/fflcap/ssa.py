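"""Exact stochastic simulation of the decoding networks.

The models are jump processes whose propensities are constant between
events except for the two input hazards, which decay monotonically in
time (exp(-t/T)).  Exactness under that time dependence is obtained by
thinning: the waiting time is proposed from the total propensity frozen
at the current (state, time) — an upper bound over the waiting interval,
because nothing increases until the next event — and the proposed event
is accepted with probability true-rate/bound, with the reaction chosen
proportionally to the true rates at the accepted time.

Optionally one kinetic parameter (by default k11, the pcFos
phosphorylation rate) is made an extrinsic random variable: a lognormal
value with median equal to the nominal rate, redrawn at absolute times
0, P_ext, 2*P_ext, ... and held constant in between, independently per
realization.  eps_noise is the sigma of the underlying normal, so
eps_noise = 0 reproduces the nominal rate exactly.

The inner loop is compiled with numba; a pure-interpreter run of the
full experiment grid would take hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numba import njit

from .inputs import InputSpec
from .networks import ReactionNetwork

__all__ = [
    "ExtrinsicNoiseSpec",
    "TrajectoryEnsemble",
    "simulate",
    "sample_extrinsic",
]

# propensity kind codes used by the compiled kernel
_MASS_ACTION = 0
_HILL = 1
_INPUT_PRODUCTION = 2
_INPUT_DEGRADATION = 3


@dataclass(frozen=True)
class ExtrinsicNoiseSpec:
    """Piecewise-constant lognormal fluctuation of one rate parameter.

    Parameters
    ----------
    target_param : str
        Name of the rate parameter to perturb (default k11).
    eps_noise : float
        Shape (sigma of the underlying normal); 0 disables the noise.
    p_ext : float
        Update period in minutes (the residence time of one drawn value).
    nominal : float
        Scale of the lognormal = median of the drawn values (default the
        nominal k11 = 0.11 /(m*min)).
    """

    target_param: str = "k11"
    eps_noise: float = 0.0
    p_ext: float = 10.0
    nominal: float = 0.11

    def __post_init__(self) -> None:
        if self.eps_noise < 0.0:
            raise ValueError("eps_noise must be >= 0")
        if self.p_ext <= 0.0:
            raise ValueError("p_ext must be positive")


def sample_extrinsic(noise: ExtrinsicNoiseSpec, rng: np.random.Generator) -> float:
    """One draw of the perturbed parameter: nominal * exp(eps * Z)."""
    return noise.nominal * float(np.exp(noise.eps_noise * rng.standard_normal()))


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Counts of one (network, input, noise) condition.

    counts has shape (n_realizations, n_sample_times, n_species) and is
    bit-exactly reproducible from the recorded per-realization seeds.
    """

    species: tuple[str, ...]
    sample_times: np.ndarray
    counts: np.ndarray
    seeds: np.ndarray
    condition: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_real, n_t, n_sp = self.counts.shape
        if n_t != self.sample_times.size or n_sp != len(self.species):
            raise ValueError("counts shape inconsistent with sample grid / species")
        if self.counts.min(initial=0) < 0:
            raise ValueError("negative counts in ensemble")

    @property
    def n_realizations(self) -> int:
        return self.counts.shape[0]

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def at(self, species: str, t: float) -> np.ndarray:
        """Per-realization counts of one species at sample time t."""
        it = int(np.argmin(np.abs(self.sample_times - t)))
        if not np.isclose(self.sample_times[it], t):
            raise ValueError(f"t={t} not on the sample grid")
        return self.counts[:, it, self.species_index(species)]

    def mean(self, species: str) -> np.ndarray:
        return self.counts[:, :, self.species_index(species)].mean(axis=0)

    def sd(self, species: str) -> np.ndarray:
        return self.counts[:, :, self.species_index(species)].std(axis=0, ddof=1)

    # -- persistence ---------------------------------------------------------

    def summary_csv(self, path) -> None:
        """Per-species ensemble mean and SD at every sample time."""
        with open(path, "w") as f:
            f.write("time_min,species,mean,sd\n")
            for j, sp in enumerate(self.species):
                m = self.counts[:, :, j].mean(axis=0)
                s = self.counts[:, :, j].std(axis=0, ddof=1)
                for t, mi, si in zip(self.sample_times, m, s):
                    f.write(f"{t:.6g},{sp},{mi:.10g},{si:.10g}\n")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts, compression="gzip")
            f.create_dataset("sample_times", data=self.sample_times)
            f.create_dataset("seeds", data=self.seeds)
            f.attrs["species"] = list(self.species)
            for k, v in self.condition.items():
                f.attrs[f"condition/{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "TrajectoryEnsemble":
        import h5py

        with h5py.File(path, "r") as f:
            condition = {
                k.split("/", 1)[1]: v
                for k, v in f.attrs.items()
                if k.startswith("condition/")
            }
            return cls(
                species=tuple(str(s) for s in f.attrs["species"]),
                sample_times=f["sample_times"][:],
                counts=f["counts"][:],
                seeds=f["seeds"][:],
                condition=condition,
            )


# -- inline counter-based RNG (xoshiro256++) ---------------------------------
# The kernel spends a large share of its time drawing waiting times and
# selection variates; an inlined xoshiro256++ stream (seeded per realization
# from a SeedSequence) is several times faster than the MT19937 the numba
# np.random shim provides, and keeps the ensembles bit-reproducible.


@njit(cache=True, inline="always")
def _rotl(v, k):
    return np.uint64((v << np.uint64(k)) | (v >> np.uint64(64 - k)))


@njit(cache=True, inline="always")
def _rng_next(state):
    s0, s1, s2, s3 = state[0], state[1], state[2], state[3]
    result = np.uint64(_rotl(np.uint64(s0 + s3), 23) + s0)
    tshift = np.uint64(s1 << np.uint64(17))
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= tshift
    s3 = _rotl(s3, 45)
    state[0], state[1], state[2], state[3] = s0, s1, s2, s3
    return result


@njit(cache=True, inline="always")
def _rng_uniform(state):
    """Uniform double in [0, 1) with 53-bit resolution."""
    return float(_rng_next(state) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always")
def _rng_exponential(state):
    u = _rng_uniform(state)
    return -np.log1p(-u)


@njit(cache=True, inline="always")
def _rng_normal(state):
    # Box-Muller; only used at extrinsic-noise update times, so the
    # discarded second variate costs nothing in practice
    u1 = _rng_uniform(state)
    while u1 <= 0.0:
        u1 = _rng_uniform(state)
    u2 = _rng_uniform(state)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True, fastmath=True)
def _ssa_one(
    kind,
    rate,
    sp1,
    sp2,
    sp3,
    hn,
    hk,
    tau,
    t_cut,
    stoich,
    aff_start,
    aff_idx,
    n_static,
    x0,
    sample_times,
    noise_rx,
    noise_base,
    eps,
    p_ext,
    rng_state,
    counts_out,
):
    """One realization; returns (n_events, n_proposals).

    Reactions 0..n_static-1 are time-independent; the (optional) last two
    rows are the input production/degradation hazards, treated as zero
    beyond their cutoff times t_cut (where they have decayed below 1e-12
    events/min).  The static total propensity is maintained incrementally
    through the per-reaction affected-reaction lists (aff_start/aff_idx,
    CSR layout).
    """
    n_rx = kind.shape[0]
    has_input = n_rx > n_static
    n_samples = sample_times.shape[0]
    t_end = sample_times[n_samples - 1]
    x = x0.copy()
    t = 0.0
    isample = 0
    n_events = 0
    n_proposals = 0

    if noise_rx >= 0:
        rate[noise_rx] = noise_base * np.exp(eps * _rng_normal(rng_state))
        next_noise = p_ext
    else:
        next_noise = np.inf

    # NOTE: the propensity switch below is spelled out inline at each use
    # site; routing it through a helper costs ~90 ns per call under numba
    # (argument marshalling defeats inlining) and dominates the whole loop.
    props = np.zeros(n_rx)
    a_static = 0.0
    for r in range(n_static):
        if kind[r] == _MASS_ACTION:
            v = rate[r]
            if sp1[r] >= 0:
                v *= x[sp1[r]]
            if sp2[r] >= 0:
                v *= x[sp2[r]]
        else:
            z = float(x[sp1[r]])
            if sp2[r] >= 0:
                z *= x[sp2[r]]
            if z <= 0.0:
                v = 0.0
            else:
                zn = z ** hn[r]
                v = rate[r] * zn / (zn + hk[r] ** hn[r])
                if sp3[r] >= 0:
                    v *= x[sp3[r]]
        props[r] = v
        a_static += v

    while True:
        # input hazards at current time (upper bound: they only decay)
        in_tot = 0.0
        if has_input:
            r_prod = n_static
            r_deg = n_static + 1
            if t < t_cut[r_prod]:
                props[r_prod] = rate[r_prod] * np.exp(-t / tau[r_prod])
            else:
                props[r_prod] = 0.0
            if x[sp1[r_deg]] > 0 and t < t_cut[r_deg]:
                props[r_deg] = rate[r_deg] * np.exp(-t / tau[r_deg])
            else:
                props[r_deg] = 0.0
            in_tot = props[r_prod] + props[r_deg]
        a_tot = a_static + in_tot
        boundary = min(next_noise, t_end)
        if a_tot <= 0.0:
            t_next = boundary
        else:
            t_next = t + _rng_exponential(rng_state) / a_tot

        if t_next >= boundary:
            while isample < n_samples and sample_times[isample] <= boundary:
                for s in range(x.shape[0]):
                    counts_out[isample, s] = x[s]
                isample += 1
            t = boundary
            if boundary >= t_end:
                return n_events, n_proposals
            # extrinsic-noise refresh of the target rate (mass-action target)
            a_static -= props[noise_rx]
            rate[noise_rx] = noise_base * np.exp(eps * _rng_normal(rng_state))
            v = rate[noise_rx]
            if sp1[noise_rx] >= 0:
                v *= x[sp1[noise_rx]]
            if sp2[noise_rx] >= 0:
                v *= x[sp2[noise_rx]]
            props[noise_rx] = v
            a_static += v
            next_noise += p_ext
            continue

        while isample < n_samples and sample_times[isample] < t_next:
            for s in range(x.shape[0]):
                counts_out[isample, s] = x[s]
            isample += 1
        t = t_next
        n_proposals += 1
        # thinning: refresh the input hazards at the accepted time (the
        # static part is unchanged, so the true total is <= a_tot)
        if has_input:
            r_prod = n_static
            r_deg = n_static + 1
            if t < t_cut[r_prod]:
                props[r_prod] = rate[r_prod] * np.exp(-t / tau[r_prod])
            else:
                props[r_prod] = 0.0
            if x[sp1[r_deg]] > 0 and t < t_cut[r_deg]:
                props[r_deg] = rate[r_deg] * np.exp(-t / tau[r_deg])
            else:
                props[r_deg] = 0.0
        u = _rng_uniform(rng_state) * a_tot
        acc = 0.0
        chosen = -1
        for r in range(n_rx):
            acc += props[r]
            if u < acc:
                chosen = r
                break
        if chosen >= 0:
            n_events += 1
            for s in range(x.shape[0]):
                x[s] += stoich[chosen, s]
                if x[s] < 0:
                    # model bug: a propensity fired at zero copy number
                    return -1, n_proposals
            # refresh the static propensities this event touched
            for j in range(aff_start[chosen], aff_start[chosen + 1]):
                r = aff_idx[j]
                a_static -= props[r]
                if kind[r] == _MASS_ACTION:
                    v = rate[r]
                    if sp1[r] >= 0:
                        v *= x[sp1[r]]
                    if sp2[r] >= 0:
                        v *= x[sp2[r]]
                else:
                    z = float(x[sp1[r]])
                    if sp2[r] >= 0:
                        z *= x[sp2[r]]
                    if z <= 0.0:
                        v = 0.0
                    else:
                        zn = z ** hn[r]
                        v = rate[r] * zn / (zn + hk[r] ** hn[r])
                        if sp3[r] >= 0:
                            v *= x[sp3[r]]
                props[r] = v
                a_static += v
            # keep the incremental sum honest against float drift
            if n_events % 65536 == 0:
                a_static = 0.0
                for r in range(n_static):
                    a_static += props[r]


def _compile_network(
    network: ReactionNetwork,
    spec: InputSpec | None,
    noise: ExtrinsicNoiseSpec | None,
):
    """Flatten a network (plus input hazards) into kernel arrays."""
    idx = {s: i for i, s in enumerate(network.species)}
    reactions = list(network.reactions)
    n_extra = 0
    if spec is not None and network.input_species is not None:
        n_extra = 2
    n_rx = len(reactions) + n_extra

    kind = np.zeros(n_rx, dtype=np.int64)
    rate = np.zeros(n_rx, dtype=np.float64)
    sp1 = np.full(n_rx, -1, dtype=np.int64)
    sp2 = np.full(n_rx, -1, dtype=np.int64)
    sp3 = np.full(n_rx, -1, dtype=np.int64)
    hn = np.zeros(n_rx, dtype=np.float64)
    hk = np.zeros(n_rx, dtype=np.float64)
    tau = np.ones(n_rx, dtype=np.float64)
    stoich = np.zeros((n_rx, len(network.species)), dtype=np.int64)
    stoich[: len(reactions)] = network.stoichiometry()

    noise_rx = -1
    for r, rx in enumerate(reactions):
        p = rx.propensity
        if p.kind == "mass_action":
            kind[r] = _MASS_ACTION
            rate[r] = p.rate
            if len(p.species) > 0:
                sp1[r] = idx[p.species[0]]
            if len(p.species) > 1:
                sp2[r] = idx[p.species[1]]
            if len(p.species) > 2:
                raise ValueError("mass action with >2 factors not supported")
        elif p.kind == "hill":
            kind[r] = _HILL
            rate[r] = p.rate
            sp1[r] = idx[p.species[0]]
            if len(p.species) > 1:
                sp2[r] = idx[p.species[1]]
            hn[r] = p.hill_n
            hk[r] = p.hill_k
            if p.mult is not None:
                sp3[r] = idx[p.mult]
        else:
            raise ValueError(f"unknown propensity kind {p.kind!r}")
        if noise is not None and p.rate_param == noise.target_param:
            if noise_rx >= 0:
                raise ValueError(
                    f"extrinsic-noise target {noise.target_param!r} is ambiguous"
                )
            if p.kind != "mass_action":
                raise ValueError("extrinsic-noise target must be a mass-action rate")
            noise_rx = r

    if noise is not None and noise_rx < 0:
        raise ValueError(
            f"extrinsic-noise target {noise.target_param!r} not found in network"
        )

    # hazard cutoff: treat an input hazard as zero once it decays below
    # 1e-12 events/min (over a 200-min run the expected number of events
    # dropped is < 2e-10)
    t_cut = np.full(n_rx, np.inf)
    if n_extra:
        i_in = idx[network.input_species]
        r = len(reactions)
        kind[r] = _INPUT_PRODUCTION
        rate[r] = spec.k1 * spec.L / spec.T1
        tau[r] = spec.T1
        stoich[r, i_in] = 1
        t_cut[r] = spec.T1 * np.log(rate[r] * 1e12)
        kind[r + 1] = _INPUT_DEGRADATION
        rate[r + 1] = spec.k2 * spec.L / spec.T2
        tau[r + 1] = spec.T2
        sp1[r + 1] = i_in
        stoich[r + 1, i_in] = -1
        t_cut[r + 1] = spec.T2 * np.log(rate[r + 1] * 1e12)

    # affected-reaction lists: for each reaction, the static reactions whose
    # propensity reads a species that reaction changes (CSR layout)
    n_static = len(reactions)
    reads: list[set[int]] = []
    for r in range(n_static):
        deps = {sp1[r], sp2[r], sp3[r]}
        deps.discard(-1)
        reads.append(deps)
    aff_start = np.zeros(n_rx + 1, dtype=np.int64)
    aff_lists = []
    for r in range(n_rx):
        changed = set(np.nonzero(stoich[r])[0])
        aff = [d for d in range(n_static) if reads[d] & changed]
        aff_lists.append(aff)
        aff_start[r + 1] = aff_start[r] + len(aff)
    aff_idx = np.array(
        [d for aff in aff_lists for d in aff] or [0], dtype=np.int64
    )[: aff_start[-1]] if aff_start[-1] else np.zeros(0, dtype=np.int64)

    return (
        kind,
        rate,
        sp1,
        sp2,
        sp3,
        hn,
        hk,
        tau,
        t_cut,
        stoich,
        noise_rx,
        aff_start,
        aff_idx,
        n_static,
    )


def simulate(
    network: ReactionNetwork,
    spec: InputSpec | None = None,
    t_end: float = 200.0,
    n_real: int = 1000,
    seed: int = 0,
    noise: ExtrinsicNoiseSpec | None = None,
    sample_dt: float = 1.0,
) -> TrajectoryEnsemble:
    """Simulate ``n_real`` exact sample paths, recorded every ``sample_dt`` min.

    ``spec`` supplies the time-inhomogeneous input hazards for the
    network's input species (omit it for autonomous networks).  The
    master ``seed`` spawns one independent stream per realization, so the
    ensemble is bit-exactly reproducible.
    """
    if t_end <= 0.0 or sample_dt <= 0.0:
        raise ValueError("t_end and sample_dt must be positive")
    if n_real < 1:
        raise ValueError("need at least one realization")

    (
        kind,
        rate,
        sp1,
        sp2,
        sp3,
        hn,
        hk,
        tau,
        t_cut,
        stoich,
        noise_rx,
        aff_start,
        aff_idx,
        n_static,
    ) = _compile_network(network, spec, noise)

    sample_times = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    x0 = network.initial_vector()
    seeds = np.random.SeedSequence(seed).generate_state(n_real, dtype=np.uint32)
    # per-realization xoshiro256++ state, one independent substream each
    rng_states = np.empty((n_real, 4), dtype=np.uint64)
    for i in range(n_real):
        rng_states[i] = np.random.SeedSequence(int(seeds[i])).generate_state(
            4, dtype=np.uint64
        )

    counts = np.zeros((n_real, sample_times.size, len(network.species)), dtype=np.int64)
    if noise is not None:
        # eps_noise = 0 still runs the update process (every draw equals the
        # nominal rate exactly), so a zero-intensity control consumes its own
        # random stream instead of replaying the unperturbed trajectory
        eps, p_ext, noise_base = noise.eps_noise, noise.p_ext, noise.nominal
    else:
        eps, p_ext, noise_base, noise_rx = 0.0, np.inf, 0.0, -1

    for i in range(n_real):
        n_ev, _ = _ssa_one(
            kind,
            rate.copy(),
            sp1,
            sp2,
            sp3,
            hn,
            hk,
            tau,
            t_cut,
            stoich,
            aff_start,
            aff_idx,
            n_static,
            x0,
            sample_times,
            noise_rx,
            noise_base,
            eps,
            p_ext,
            rng_states[i],
            counts[i],
        )
        if n_ev < 0:
            raise RuntimeError(
                f"negative count reached in realization {i} of {network.name!r} "
                "(propensity fired at zero copy number: model bug)"
            )

    condition: dict[str, Any] = {"network": network.name, "seed": seed}
    if spec is not None:
        condition.update(input=spec.label, L=spec.L)
    if noise is not None:
        condition.update(eps_noise=noise.eps_noise, p_ext=noise.p_ext)
    return TrajectoryEnsemble(
        species=network.species,
        sample_times=sample_times,
        counts=counts,
        seeds=seeds,
        condition=condition,
    )
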