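"""Synthetic channels and ensembles with closed-form ground truth.

These generators exercise the estimation and information stages without
simulating the full pathway: channels whose capacity is known in closed
form (identity, binary symmetric, symmetric, uniform-row), and sampled
ensembles with known laws (per-input Poisson counts, deterministic maps,
and a linear birth-death process whose stationary distribution is
Poisson(k/g)).  They emulate statistical structure only, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .infotheory import DiscreteChannel
from .networks import ReactionNetwork, _ma
from .ssa import TrajectoryEnsemble, simulate

__all__ = ["FixtureSpec", "make_channel", "make_ensemble", "birth_death_network"]


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic fixture.

    kind
        "identity" | "bsc" | "symmetric" (channels with closed-form
        capacity) or "poisson_map" | "deterministic_map" | "birth_death"
        (ensembles with known laws).
    parameters
        kind-specific: "crossover" (bsc), "row" (symmetric), "lams"
        (poisson_map), "levels" (deterministic_map), "birth"/"death"
        (birth_death).
    """

    kind: str
    n_inputs: int = 2
    n_samples: int = 1000
    seed: int = 0
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_inputs < 1:
            raise ValueError("need n_samples >= 1 and n_inputs >= 1")


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def make_channel(spec: FixtureSpec) -> tuple[DiscreteChannel, float]:
    """A channel plus its closed-form capacity in bits.

    identity: C = log2(n).  bsc: C = 1 - H2(crossover).  symmetric (all
    rows permutations of one row): C = log2(n_outputs) - H(row).
    """
    if spec.kind == "identity":
        n = spec.n_inputs
        cond = np.eye(n)
        return (
            DiscreteChannel(tuple(range(n)), cond, provenance={"kind": "identity"}),
            float(np.log2(n)),
        )
    if spec.kind == "bsc":
        p = float(spec.parameters.get("crossover", 0.25))
        if not 0.0 <= p <= 1.0:
            raise ValueError("crossover must be in [0, 1]")
        cond = np.array([[1 - p, p], [p, 1 - p]])
        return (
            DiscreteChannel((0, 1), cond, provenance={"kind": "bsc", "crossover": p}),
            1.0 - _entropy_bits([p, 1 - p]),
        )
    if spec.kind == "symmetric":
        row = np.asarray(spec.parameters["row"], dtype=float)
        if abs(row.sum() - 1.0) > 1e-12 or row.min() < 0:
            raise ValueError("row must be a probability vector")
        n = row.size
        cond = np.array([np.roll(row, j) for j in range(n)])
        return (
            DiscreteChannel(tuple(range(n)), cond, provenance={"kind": "symmetric"}),
            float(np.log2(n)) - _entropy_bits(row),
        )
    raise ValueError(f"no closed-form channel for kind {spec.kind!r}")


def birth_death_network(birth: float = 20.0, death: float = 0.1) -> ReactionNetwork:
    """Linear birth-death process; stationary law Poisson(birth/death)."""
    return ReactionNetwork(
        name="birth_death",
        species=("X",),
        reactions=(
            _ma("birth", birth, {}, {"X": 1}, []),
            _ma("death", death, {"X": 1}, {}, ["X"]),
        ),
        params={"birth": birth, "death": death},
    )


def _wrap_counts(counts_1d: np.ndarray, seed: int, label: Any, kind: str) -> TrajectoryEnsemble:
    n = counts_1d.size
    return TrajectoryEnsemble(
        species=("X",),
        sample_times=np.array([0.0]),
        counts=counts_1d.reshape(n, 1, 1).astype(np.int64),
        seeds=np.array([seed], dtype=np.uint32),
        condition={"fixture": kind, "input": label},
    )


def make_ensemble(spec: FixtureSpec) -> dict[Any, TrajectoryEnsemble]:
    """Sampled ensembles keyed by input label, tagged with their law.

    poisson_map: input j yields Poisson(lam_j) counts (lams default
    10*(j+1)).  deterministic_map: input j yields the constant
    levels[j] (default 100*(j+1)) — zero-variance ensembles.
    birth_death: a single SSA ensemble of the linear birth-death
    process (stationary Poisson(birth/death)).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "poisson_map":
        lams = spec.parameters.get(
            "lams", [10.0 * (j + 1) for j in range(spec.n_inputs)]
        )
        return {
            j: _wrap_counts(
                rng.poisson(lams[j], size=spec.n_samples), spec.seed, j, spec.kind
            )
            for j in range(spec.n_inputs)
        }
    if spec.kind == "deterministic_map":
        levels = spec.parameters.get(
            "levels", [100 * (j + 1) for j in range(spec.n_inputs)]
        )
        return {
            j: _wrap_counts(
                np.full(spec.n_samples, levels[j]), spec.seed, j, spec.kind
            )
            for j in range(spec.n_inputs)
        }
    if spec.kind == "birth_death":
        birth = float(spec.parameters.get("birth", 20.0))
        death = float(spec.parameters.get("death", 0.1))
        t_end = float(spec.parameters.get("t_end", 200.0))
        ens = simulate(
            birth_death_network(birth, death),
            spec=None,
            t_end=t_end,
            n_real=spec.n_samples,
            seed=spec.seed,
        )
        return {"birth_death": ens}
    raise ValueError(f"no ensemble generator for kind {spec.kind!r}")
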