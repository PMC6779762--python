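"""Deterministic mean-field integration of the decoding networks.

The mean-field right-hand side is reconstructed from each network's
reactions (net stoichiometry times propensity evaluated on continuous
levels), with the input species prescribed by the closed-form trace
rather than integrated.  This serves two roles: a validation oracle for
the stochastic engine (ensemble means of abundant species must track the
ODE solution) and a source of steady-state values for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .inputs import InputSpec
from .networks import ReactionNetwork

__all__ = ["OdeSolution", "integrate", "steady_state"]

# stand-in level for species that grow without bound when solving for the
# asymptotic fixed point of the remaining system
_DIVERGENT_CLAMP = 1e12


@dataclass(frozen=True)
class OdeSolution:
    network: str
    species: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray  # (time, species)
    rtol: float
    atol: float

    def of(self, species: str) -> np.ndarray:
        return self.values[:, self.species.index(species)]

    def at(self, species: str, t) -> np.ndarray:
        return np.interp(t, self.times, self.of(species))

    def to_csv(self, path) -> None:
        """Write the solution as CSV (time, one column per species)."""
        with open(path, "w") as f:
            f.write("time_min," + ",".join(self.species) + "\n")
            for i, t in enumerate(self.times):
                row = ",".join(f"{v:.10g}" for v in self.values[i])
                f.write(f"{t:.6g},{row}\n")


def _make_rhs(network: ReactionNetwork, spec: InputSpec | None):
    species = network.species
    stoich = network.stoichiometry().astype(float)  # (rx, sp)
    i_in = (
        species.index(network.input_species)
        if network.input_species is not None
        else -1
    )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        state = dict(zip(species, y))
        if i_in >= 0:
            state[species[i_in]] = spec.eval(t) if spec is not None else 0.0
        props = np.array([rx.propensity.value(state) for rx in network.reactions])
        dy = props @ stoich
        if i_in >= 0:
            dy[i_in] = spec.deriv(t) if spec is not None else 0.0
        return dy

    return rhs, i_in


def integrate(
    network: ReactionNetwork,
    spec: InputSpec | None = None,
    t_end: float = 200.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_dt: float = 1.0,
) -> OdeSolution:
    """Solve the mean-field ODEs on [0, t_end] from the network's initial
    state, with the input species following its closed-form trace."""
    rhs, i_in = _make_rhs(network, spec)
    y0 = network.initial_vector().astype(float)
    if i_in >= 0 and spec is not None:
        y0[i_in] = spec.eval(0.0)
    t_eval = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed for {network.name!r}: {sol.message}")
    values = sol.y.T.copy()
    if i_in >= 0:
        values[:, i_in] = spec.eval(sol.t) if spec is not None else 0.0
    if values.min() < -1e3 * atol:
        raise RuntimeError("negative state beyond tolerance in ODE solution")
    return OdeSolution(network.name, network.species, sol.t, values, rtol, atol)


def _divergent_species(network: ReactionNetwork) -> set[str]:
    """Species that no reaction removes: they accumulate without bound
    whenever their production stays active (e.g. DUSP in the MAPK model)."""
    removed = set()
    for rx in network.reactions:
        for s, d in rx.net_change().items():
            if d < 0:
                removed.add(s)
    produced = set()
    for rx in network.reactions:
        for s, d in rx.net_change().items():
            if d > 0:
                produced.add(s)
    return produced - removed


def steady_state(
    network: ReactionNetwork,
    spec: InputSpec | None = None,
    t_seed: float = 2000.0,
    tol: float = 1e-9,
) -> dict[str, float]:
    """Long-time fixed point of the mean-field system, with the input held
    at its asymptotic level A_N.

    Species that the network never degrades are reported as ``inf``
    (divergent); the remaining system is solved with the divergent pool
    clamped at a large level, which drives the species it consumes to
    their asymptotic limits.
    """
    species = network.species
    i_in = (
        species.index(network.input_species)
        if network.input_species is not None
        else -1
    )
    a_inf = spec.amplitude if spec is not None else 0.0
    divergent = _divergent_species(network)
    stoich = network.stoichiometry().astype(float)

    free = [
        i
        for i, s in enumerate(species)
        if i != i_in and s not in divergent
    ]

    def residual(y_free: np.ndarray) -> np.ndarray:
        state = {}
        for i, s in enumerate(species):
            if i == i_in:
                state[s] = a_inf
            elif s in divergent:
                state[s] = _DIVERGENT_CLAMP
            else:
                state[s] = 0.0
        for j, i in enumerate(free):
            state[species[i]] = y_free[j]
        props = np.array([rx.propensity.value(state) for rx in network.reactions])
        dy = props @ stoich
        return dy[free]

    # seed the root solve from a long integration
    seed_sol = integrate(network, spec, t_end=t_seed, rtol=1e-8, atol=1e-10, sample_dt=t_seed / 200)
    y_seed = seed_sol.values[-1, free]

    res = root(residual, y_seed, method="hybr", tol=tol)
    if not res.success or np.max(np.abs(residual(res.x))) > 1e-6:
        raise RuntimeError(f"steady-state solve failed for {network.name!r}: {res.message}")

    out: dict[str, float] = {}
    for i, s in enumerate(species):
        if i == i_in:
            out[s] = a_inf
        elif s in divergent:
            out[s] = np.inf
        else:
            out[s] = float(res.x[free.index(i)])
    return out
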