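"""Reaction networks of the decoding models.

Four stochastic models are built here, all parameterized from a single
rate table (`TABLE1`):

* the MAPK/ERK decoding section (ppERK import, DUSP feedback, RSK,
  cFos transcription/translation and pcFos stabilization — two nested
  coherent type-I feed-forward loops);
* a minimal decoder of four identical proteins B..E wired in the same
  nested-FFL topology, with propensities normalized so every protein
  shares the steady state SS = A_N * G_N;
* its linear-chain control (D and E read only their direct upstream
  neighbour);
* a two-state-promoter reporter gene (Hill activation by a chosen
  transcription factor, constitutive transcription/translation).

Stoichiometry follows the deterministic rate equations of the models:
activation steps that appear as "X -> Y" in the rate table but carry no
loss term for X in the ODEs are implemented catalytically (X is read,
not consumed).  Concentration units ("m") map 1:1 to molecule counts, as
in the published stochastic implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inputs import InputSpec

__all__ = [
    "TABLE1",
    "Propensity",
    "Reaction",
    "ReactionNetwork",
    "AffinityVariant",
    "build_mapk_network",
    "build_minimal_network",
    "build_linear_chain_network",
    "build_gene_network",
    "compose",
]


#: Published kinetic parameters of the three stochastic models.
TABLE1: dict[str, dict[str, float]] = {
    "mapk": {
        "k1": 15.0,   # ppERK nuclear import, 1/min
        "k": 1.0,     # DUSP production, 1/min
        "k2": 50.0,   # ppERK_nuc export/dephosphorylation, 1/min
        "k3": 14.0,   # DUSP-mediated dephosphorylation, 1/min
        "k4": 0.1,    # nuclear RSK activation, 1/min
        "k5": 0.15,   # RSK inactivation, 1/min
        "n": 1.1,     # Hill exponent of cFos_pre production
        "k6": 0.13,   # Hill half-saturation of cFos_pre production, m^2
        "k7": 0.5,    # pre-mRNA processing, 1/min
        "k8": 0.08,   # cFos mRNA degradation, 1/min
        "k9": 0.3,    # translation, 1/min
        "k10": 0.3,   # cFos degradation, 1/min
        "k11": 0.11,  # cFos stabilization by ppERK_cyt, 1/(m*min)
        "k12": 0.001, # pcFos degradation, 1/min
        "k13": 0.6,   # pcFos inactivation, 1/min
    },
    "minimal": {
        "k": 20.0,    # production rate of every protein, 1/min
        "g": 0.1,     # dilution/degradation of every protein, 1/min
    },
    "gene": {
        "kappa_pm": 0.1,  # promoter activation, 1/min
        "n_g": 2.0,       # promoter Hill exponent
        "K_rp": 100.0,    # inverse promoter affinity, m
        "gamma_pm": 0.2,  # promoter inactivation, 1/min
        "kappa_m": 14.0,  # transcription, 1/min
        "gamma_m": 1.0,   # mRNA degradation, 1/min
        "kappa_p": 20.0,  # translation, 1/min
        "gamma_p": 0.1,   # protein loss, 1/min
    },
}


@dataclass(frozen=True)
class Propensity:
    """Event-rate rule of one reaction.

    kind
        ``"mass_action"``: rate * prod(counts of `species`);
        ``"hill"``: rate * z^n / (z^n + K^n) * count(mult), with
        z = prod(counts of `species`) and `mult` optional;
        the time-inhomogeneous input hazards live in the simulation
        engine, not here.
    rate_param
        Optional name tying `rate` back to the parameter table (used to
        target extrinsic-noise perturbations).
    """

    kind: str
    rate: float
    species: tuple[str, ...] = ()
    hill_n: float = 0.0
    hill_k: float = 0.0
    mult: str | None = None
    rate_param: str | None = None

    def value(self, state: dict[str, float]) -> float:
        """Evaluate on a (possibly continuous) state; used by the ODE
        engine and by tests — the SSA kernel has its own compiled path."""
        if self.kind == "mass_action":
            v = self.rate
            for s in self.species:
                v *= state[s]
            return v
        if self.kind == "hill":
            z = 1.0
            for s in self.species:
                z *= state[s]
            if z <= 0.0:
                return 0.0
            zn = z ** self.hill_n
            v = self.rate * zn / (zn + self.hill_k ** self.hill_n)
            if self.mult is not None:
                v *= state[self.mult]
            return v
        raise ValueError(f"unknown propensity kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    name: str
    consumed: dict[str, int]
    produced: dict[str, int]
    propensity: Propensity

    def net_change(self) -> dict[str, int]:
        delta: dict[str, int] = {}
        for s, c in self.consumed.items():
            delta[s] = delta.get(s, 0) - c
        for s, c in self.produced.items():
            delta[s] = delta.get(s, 0) + c
        return delta


@dataclass(frozen=True)
class ReactionNetwork:
    """A named set of species and reactions with kinetic parameters.

    ``input_species`` names the species driven by the prescribed input
    hazards (None for autonomous networks such as test fixtures).
    """

    name: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    params: dict[str, float] = field(default_factory=dict)
    initial_state: dict[str, int] = field(default_factory=dict)
    input_species: str | None = None

    def __post_init__(self) -> None:
        declared = set(self.species)
        for rx in self.reactions:
            used = (
                set(rx.consumed)
                | set(rx.produced)
                | set(rx.propensity.species)
                | ({rx.propensity.mult} if rx.propensity.mult else set())
            )
            missing = used - declared
            if missing:
                raise ValueError(f"reaction {rx.name!r} references undeclared species {missing}")
        if self.input_species is not None and self.input_species not in declared:
            raise ValueError(f"input species {self.input_species!r} not declared")
        for s, c in self.initial_state.items():
            if s not in declared:
                raise ValueError(f"initial state for undeclared species {s!r}")
            if c < 0:
                raise ValueError("initial counts must be non-negative")

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def initial_vector(self) -> np.ndarray:
        return np.array(
            [self.initial_state.get(s, 0) for s in self.species], dtype=np.int64
        )

    def stoichiometry(self) -> np.ndarray:
        """(n_reactions, n_species) net state change per event."""
        mat = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        idx = {s: i for i, s in enumerate(self.species)}
        for r, rx in enumerate(self.reactions):
            for s, d in rx.net_change().items():
                mat[r, idx[s]] = d
        return mat

    def propensities(self, state: dict[str, float]) -> np.ndarray:
        return np.array([rx.propensity.value(state) for rx in self.reactions])

    def describe(self) -> str:
        """Human-readable model listing (species, reactions, parameters)."""
        lines = [f"network: {self.name}", f"species: {', '.join(self.species)}"]
        if self.input_species:
            lines.append(f"input species: {self.input_species}")
        if self.initial_state:
            init = ", ".join(f"{s}={c}" for s, c in self.initial_state.items())
            lines.append(f"initial state (others 0): {init}")
        lines.append("reactions:")
        for rx in self.reactions:
            p = rx.propensity
            delta = ", ".join(f"{s}{d:+d}" for s, d in sorted(rx.net_change().items()))
            if p.kind == "mass_action":
                form = f"{p.rate:g} * " + " * ".join(p.species) if p.species else f"{p.rate:g}"
            else:
                z = "*".join(p.species)
                form = f"{p.rate:g} * ({z})^{p.hill_n:g} / (({z})^{p.hill_n:g} + {p.hill_k:g}^{p.hill_n:g})"
                if p.mult:
                    form += f" * {p.mult}"
            lines.append(f"  {rx.name}: [{delta or 'no net change'}]  rate = {form}")
        if self.params:
            lines.append("parameters:")
            for k, v in self.params.items():
                lines.append(f"  {k} = {v:g}")
        return "\n".join(lines) + "\n"

    def to_text(self, path) -> None:
        with open(path, "w") as f:
            f.write(self.describe())


@dataclass(frozen=True)
class AffinityVariant:
    """Promoter-affinity variant: K_rp is multiplied by `scale`.

    H (high affinity) = 0.1, N (nominal) = 1.0, L (low affinity) = 10.0 —
    affinity is the inverse of K_rp, so a smaller scale binds tighter.
    """

    scale: float = 1.0
    tag: str = "N"

    def __post_init__(self) -> None:
        if self.scale <= 0.0:
            raise ValueError("affinity scale must be positive")

    @classmethod
    def high(cls) -> "AffinityVariant":
        return cls(0.1, "H")

    @classmethod
    def nominal(cls) -> "AffinityVariant":
        return cls(1.0, "N")

    @classmethod
    def low(cls) -> "AffinityVariant":
        return cls(10.0, "L")


def _ma(name, rate, consumed, produced, species, rate_param=None) -> Reaction:
    return Reaction(
        name,
        consumed,
        produced,
        Propensity("mass_action", rate, tuple(species), rate_param=rate_param),
    )


def build_mapk_network() -> ReactionNetwork:
    """Decoding section of the MAPK/ERK pathway (two nested coherent FFLs).

    ppERK_cyt is the prescribed input (driven by the input hazards only);
    import, DUSP production, RSK activation and cFos_pre production are
    catalytic reads, matching the deterministic rate equations.  DUSP has
    production but no decay, so it accumulates for as long as ppERK_nuc
    is present — this is the published model's negative-feedback arm.
    """
    p = TABLE1["mapk"]
    species = (
        "ppERK_cyt",
        "ppERK_nuc",
        "DUSP",
        "pRSK_nuc",
        "cFos_pre",
        "cFos_m",
        "cFos",
        "pcFos",
    )
    reactions = (
        # nuclear import reads the prescribed cytoplasmic pool
        _ma("import", p["k1"], {}, {"ppERK_nuc": 1}, ["ppERK_cyt"], "k1"),
        _ma("dusp_production", p["k"], {}, {"DUSP": 1}, ["ppERK_nuc"], "k"),
        _ma("pperk_nuc_export", p["k2"], {"ppERK_nuc": 1}, {}, ["ppERK_nuc"], "k2"),
        _ma(
            "dusp_dephosphorylation",
            p["k3"],
            {"ppERK_nuc": 1},
            {},
            ["DUSP", "ppERK_nuc"],
            "k3",
        ),
        _ma("rsk_activation", p["k4"], {}, {"pRSK_nuc": 1}, ["ppERK_nuc"], "k4"),
        _ma("rsk_inactivation", p["k5"], {"pRSK_nuc": 1}, {}, ["pRSK_nuc"], "k5"),
        # transcription of the primary cFos transcript: Hill function of the
        # ppERK_nuc * pRSK_nuc product, unit prefactor as printed
        Reaction(
            "cfos_pre_production",
            {},
            {"cFos_pre": 1},
            Propensity(
                "hill",
                1.0,
                ("ppERK_nuc", "pRSK_nuc"),
                hill_n=p["n"],
                hill_k=p["k6"],
            ),
        ),
        _ma("mrna_processing", p["k7"], {"cFos_pre": 1}, {"cFos_m": 1}, ["cFos_pre"], "k7"),
        _ma("mrna_degradation", p["k8"], {"cFos_m": 1}, {}, ["cFos_m"], "k8"),
        _ma("translation", p["k9"], {}, {"cFos": 1}, ["cFos_m"], "k9"),
        _ma("cfos_degradation", p["k10"], {"cFos": 1}, {}, ["cFos"], "k10"),
        _ma(
            "cfos_stabilization",
            p["k11"],
            {"cFos": 1},
            {"pcFos": 1},
            ["ppERK_cyt", "cFos"],
            "k11",
        ),
        _ma("pcfos_degradation", p["k12"], {"pcFos": 1}, {}, ["pcFos"], "k12"),
        _ma("pcfos_inactivation", p["k13"], {"pcFos": 1}, {"cFos": 1}, ["pcFos"], "k13"),
    )
    return ReactionNetwork(
        name="mapk",
        species=species,
        reactions=reactions,
        params=dict(p),
        initial_state={},
        input_species="ppERK_cyt",
    )


def _minimal_like(name: str, spec: InputSpec, ffl: bool) -> ReactionNetwork:
    p = TABLE1["minimal"]
    k, g = p["k"], p["g"]
    A_N = spec.amplitude
    if A_N <= 0.0:
        raise ValueError("minimal model requires a positive input amplitude (k1 > k2)")
    G_N = k / g
    species = ("A", "B", "C", "D", "E")
    reactions = [
        _ma("B_production", k, {}, {"B": 1}, ["A"], "k"),
        _ma("B_decay", g, {"B": 1}, {}, ["B"], "g"),
        _ma("C_production", k / G_N, {}, {"C": 1}, ["B"], "k"),
        _ma("C_decay", g, {"C": 1}, {}, ["C"], "g"),
    ]
    if ffl:
        reactions += [
            _ma("D_production", k / (A_N * G_N**2), {}, {"D": 1}, ["B", "C"], "k"),
            _ma("D_decay", g, {"D": 1}, {}, ["D"], "g"),
            _ma("E_production", k / (A_N * G_N**2), {}, {"E": 1}, ["C", "D"], "k"),
            _ma("E_decay", g, {"E": 1}, {}, ["E"], "g"),
        ]
    else:
        reactions += [
            _ma("D_production", k / G_N, {}, {"D": 1}, ["C"], "k"),
            _ma("D_decay", g, {"D": 1}, {}, ["D"], "g"),
            _ma("E_production", k / G_N, {}, {"E": 1}, ["D"], "k"),
            _ma("E_decay", g, {"E": 1}, {}, ["E"], "g"),
        ]
    return ReactionNetwork(
        name=name,
        species=species,
        reactions=tuple(reactions),
        params={**p, "A_N": A_N, "G_N": G_N},
        initial_state={},
        input_species="A",
    )


def build_minimal_network(spec: InputSpec) -> ReactionNetwork:
    """Minimal decoder: proteins B..E in two nested FFLs.

    The bilinear production propensities of D and E are normalized by
    A_N * G_N^2 (A_N = L*(k1-k2) of the driving input, G_N = k/g) so that
    every protein's steady state equals SS = A_N * G_N — amplification is
    deliberately removed, leaving only the topology.
    """
    return _minimal_like("minimal", spec, ffl=True)


def build_linear_chain_network(spec: InputSpec) -> ReactionNetwork:
    """Linear-chain control: same species and rates, but D reads only C
    and E reads only D (no feed-forward edges)."""
    return _minimal_like("linear_chain", spec, ffl=False)


def build_gene_network(
    tf_species: str = "pcFos",
    variant: AffinityVariant | None = None,
    name: str = "gene",
) -> ReactionNetwork:
    """Two-state-promoter reporter gene activated by ``tf_species``.

    Single promoter copy: the inactive form starts at 1 and the active +
    inactive counts are conserved.  Activation is a Hill function of the
    transcription factor with half-saturation scale*K_rp; the reporter
    protein in isolation (promoter always on) would settle at
    kappa_m*kappa_p/(gamma_m*gamma_p) = 2800 copies.

    Gene-local species are namespaced as ``{name}:...`` so several
    reporters can coexist; the TF itself is shared (read catalytically).
    """
    if variant is None:
        variant = AffinityVariant.nominal()
    p = TABLE1["gene"]
    off, on, m, prot = (f"{name}:P*", f"{name}:Pm", f"{name}:m", f"{name}:P")
    reactions = (
        Reaction(
            f"{name}:activation",
            {off: 1},
            {on: 1},
            Propensity(
                "hill",
                p["kappa_pm"],
                (tf_species,),
                hill_n=p["n_g"],
                hill_k=variant.scale * p["K_rp"],
                mult=off,
                rate_param="kappa_pm",
            ),
        ),
        _ma(f"{name}:inactivation", p["gamma_pm"], {on: 1}, {off: 1}, [on], "gamma_pm"),
        _ma(f"{name}:transcription", p["kappa_m"], {}, {m: 1}, [on], "kappa_m"),
        _ma(f"{name}:mrna_decay", p["gamma_m"], {m: 1}, {}, [m], "gamma_m"),
        _ma(f"{name}:translation", p["kappa_p"], {}, {prot: 1}, [m], "kappa_p"),
        _ma(f"{name}:protein_decay", p["gamma_p"], {prot: 1}, {}, [prot], "gamma_p"),
    )
    return ReactionNetwork(
        name=name,
        species=(tf_species, off, on, m, prot),
        reactions=reactions,
        params={**p, "affinity_scale": variant.scale},
        initial_state={off: 1},
        input_species=None,
    )


def compose(host: ReactionNetwork, *genes: ReactionNetwork) -> ReactionNetwork:
    """Couple reporter genes to a host network.

    Each gene's TF species must exist in the host; genes read it
    catalytically, so the host dynamics are unchanged by the coupling.
    Gene-local species keep their namespaced names and must not clash.
    """
    species = list(host.species)
    seen = set(species)
    reactions = list(host.reactions)
    params = dict(host.params)
    initial = dict(host.initial_state)
    for gene in genes:
        local = [s for s in gene.species if s not in host.species]
        tf = [s for s in gene.species if s in host.species]
        if not tf:
            raise ValueError(
                f"gene {gene.name!r}: no species shared with host "
                f"{host.name!r} (unknown transcription factor?)"
            )
        clash = set(local) & seen
        if clash:
            raise ValueError(f"species name clash composing {gene.name!r}: {clash}")
        species.extend(local)
        seen.update(local)
        reactions.extend(gene.reactions)
        for key, val in gene.params.items():
            params[f"{gene.name}:{key}"] = val
        for s, c in gene.initial_state.items():
            initial[s] = c
    return ReactionNetwork(
        name=host.name + "+" + "+".join(g.name for g in genes),
        species=tuple(species),
        reactions=tuple(reactions),
        params=params,
        initial_state=initial,
        input_species=host.input_species,
    )
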