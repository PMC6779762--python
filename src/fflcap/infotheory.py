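"""Channel estimation, mutual information, capacity and noise readouts.

The stimulus S is the input scale L (a finite set of levels); the
response R is the molecule count of one species at one sample time.
Per-level response histograms on a shared equal-width partition of the
pooled range form the conditional matrix P(R=r_i | S=s_j); mutual
information, the Blahut-Arimoto channel capacity and the multivariate
mutual information of several reporters (assuming conditional
independence given S) are computed from that matrix in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .ssa import TrajectoryEnsemble

__all__ = [
    "DiscreteChannel",
    "CapacityResult",
    "estimate_channel",
    "channel_from_samples",
    "mutual_information",
    "arimoto_blahut",
    "cc_timeseries",
    "mmi",
    "joint_channel",
    "coefficient_of_variation",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class DiscreteChannel:
    """Conditional response matrix P(R=r_i | S=s_j), rows indexed by input."""

    input_labels: tuple
    cond: np.ndarray  # (n_inputs, n_bins)
    bin_edges: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cond = np.asarray(self.cond, dtype=float)
        if cond.ndim != 2 or cond.shape[0] != len(self.input_labels):
            raise ValueError("cond must be (n_inputs, n_bins)")
        if cond.min() < 0.0:
            raise ValueError("negative conditional probability")
        if np.max(np.abs(cond.sum(axis=1) - 1.0)) > _ROW_TOL:
            raise ValueError("channel rows must sum to 1")

    @property
    def n_inputs(self) -> int:
        return self.cond.shape[0]

    @property
    def n_bins(self) -> int:
        return self.cond.shape[1]

    def to_csv(self, path) -> None:
        """Conditional matrix as CSV plus a JSON sidecar (``<path>.json``)
        carrying bin edges, input labels and provenance."""
        import json

        with open(path, "w") as f:
            f.write("input," + ",".join(f"bin{i}" for i in range(self.n_bins)) + "\n")
            for label, row in zip(self.input_labels, self.cond):
                f.write(str(label) + "," + ",".join(f"{v:.10g}" for v in row) + "\n")
        sidecar = {
            "input_labels": [float(x) if isinstance(x, (int, float)) else str(x)
                             for x in self.input_labels],
            "bin_edges": None if self.bin_edges is None else list(map(float, self.bin_edges)),
            "provenance": {k: str(v) for k, v in self.provenance.items()},
        }
        with open(str(path) + ".json", "w") as f:
            json.dump(sidecar, f, indent=2)


@dataclass(frozen=True)
class CapacityResult:
    cc_bits: float
    p_star: np.ndarray
    iterations: int
    gap_bits: float
    converged: bool


def channel_from_samples(
    samples_by_input: Mapping[Any, np.ndarray],
    bins: int = 64,
    provenance: dict | None = None,
) -> DiscreteChannel:
    """Histogram channel from raw per-input response samples.

    The pooled min-max range over all inputs is split into ``bins``
    equal-width cells shared by every input; each row is that input's
    normalized histogram.  A degenerate pooled range (all observations
    identical) yields a valid single-bin channel.
    """
    labels = tuple(samples_by_input.keys())
    if len(labels) < 1:
        raise ValueError("need at least one input level")
    arrays = [np.asarray(samples_by_input[s], dtype=float) for s in labels]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty sample set for some input")
    lo = min(a.min() for a in arrays)
    hi = max(a.max() for a in arrays)
    if hi <= lo:
        cond = np.ones((len(labels), 1))
        edges = np.array([lo, lo + 1.0])
    else:
        edges = np.linspace(lo, hi, bins + 1)
        cond = np.empty((len(labels), bins))
        for j, a in enumerate(arrays):
            h, _ = np.histogram(a, bins=edges)
            cond[j] = h / a.size
    return DiscreteChannel(labels, cond, edges, provenance or {})


def estimate_channel(
    ensembles: Mapping[Any, TrajectoryEnsemble],
    species: str,
    t: float,
    bins: int = 64,
) -> DiscreteChannel:
    """Channel of one species at one sample time across input levels."""
    if len(ensembles) < 2:
        raise ValueError("need at least two input levels for a channel")
    grids = [e.sample_times for e in ensembles.values()]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("ensembles must share the sample grid")
    samples = {s: e.at(species, t) for s, e in ensembles.items()}
    return channel_from_samples(
        samples, bins=bins, provenance={"species": species, "t": t, "bins": bins}
    )


def _xlogy2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """x * log2(y) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    mask = x > 0
    out[mask] = x[mask] * np.log2(y[mask])
    return out


def mutual_information(p_s: np.ndarray, channel: DiscreteChannel) -> float:
    """I(R;S) in bits for input distribution ``p_s`` over the channel rows."""
    p_s = np.asarray(p_s, dtype=float)
    if p_s.shape != (channel.n_inputs,):
        raise ValueError("p_s does not match the channel inputs")
    if p_s.min() < 0 or abs(p_s.sum() - 1.0) > 1e-9:
        raise ValueError("p_s must be a probability distribution")
    cond = channel.cond
    p_r = p_s @ cond
    terms = np.zeros_like(cond)
    mask = (cond > 0) & (p_s[:, None] > 0)
    terms[mask] = (p_s[:, None] * cond)[mask] * np.log2(
        cond[mask] / np.broadcast_to(p_r, cond.shape)[mask]
    )
    return float(terms.sum())


def arimoto_blahut(
    channel: DiscreteChannel,
    tol_bits: float = 1e-6,
    max_iter: int = 10_000,
) -> CapacityResult:
    """Capacity and maximizing input distribution by Blahut-Arimoto.

    Alternates the posterior update q(s|r) ∝ p(s) W(r|s) with the input
    update p(s) ∝ exp(Σ_r W(r|s) ln q(s|r)) from a uniform start, until
    the standard upper/lower capacity bounds pinch below ``tol_bits``:
    the lower bound is I(p, W); the upper bound is max_s D(W(·|s) || p_R).
    """
    if tol_bits <= 0:
        raise ValueError("tol_bits must be positive")
    W = channel.cond
    n_s = channel.n_inputs
    p = np.full(n_s, 1.0 / n_s)
    ln2 = np.log(2.0)

    lower = upper = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        p_r = p @ W  # output distribution
        # D(W(.|s) || p_r) per input, in bits
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.where(W > 0, np.log(W / np.maximum(p_r, 1e-300)), 0.0)
        d = (W * logratio).sum(axis=1) / ln2
        lower = float(p @ d)
        upper = float(d.max())
        if upper - lower < tol_bits:
            return CapacityResult(lower, p, it, upper - lower, True)
        # exponentiated-divergence update (log-domain for stability)
        logp = np.log(np.maximum(p, 1e-300)) + d * ln2
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
    return CapacityResult(lower, p, it, upper - lower, False)


def cc_timeseries(
    ensembles: Mapping[Any, TrajectoryEnsemble],
    species: str,
    bins: int = 64,
    tol_bits: float = 1e-6,
    times: Sequence[float] | None = None,
) -> tuple[np.ndarray, list[CapacityResult]]:
    """Channel capacity of one species at every sample time (or ``times``)."""
    first = next(iter(ensembles.values()))
    tgrid = np.asarray(times if times is not None else first.sample_times, dtype=float)
    results = []
    for t in tgrid:
        ch = estimate_channel(ensembles, species, t, bins=bins)
        results.append(arimoto_blahut(ch, tol_bits=tol_bits))
    return tgrid, results


def joint_channel(channels: Sequence[DiscreteChannel]) -> DiscreteChannel:
    """Factorized joint channel of several reporters read simultaneously.

    Conditional independence given the input is assumed:
    P(r_1..r_n | s) = Π_i P(r_i | s).  All-zero joint cells are dropped,
    which changes nothing information-theoretically and keeps the support
    tractable.
    """
    labels = channels[0].input_labels
    for ch in channels[1:]:
        if ch.input_labels != labels:
            raise ValueError("channels must share input labels")
    cells = 1
    for ch in channels:
        cells *= ch.n_bins
    if cells > 10**7:
        raise ValueError(
            f"joint support of {cells} cells is intractable; use coarser binning"
        )
    joint = channels[0].cond
    for ch in channels[1:]:
        joint = joint[:, :, None] * ch.cond[:, None, :]
        joint = joint.reshape(len(labels), -1)
    keep = joint.sum(axis=0) > 0
    joint = joint[:, keep]
    # renormalize away float round-off so rows sum to 1 exactly
    joint = joint / joint.sum(axis=1, keepdims=True)
    return DiscreteChannel(labels, joint, None, {"joint_of": len(channels)})


def mmi(
    channels: Sequence[DiscreteChannel],
    p_s: np.ndarray | None = None,
    tol_bits: float = 1e-6,
) -> float:
    """Multivariate mutual information I(R_1..R_n; S) in bits.

    With ``p_s`` omitted, the capacity-achieving distribution of the
    factorized joint channel is used (the MMI then equals that channel's
    capacity, the ceiling of jointly extractable information).  A single
    channel reduces exactly to ``mutual_information``.
    """
    joint = joint_channel(list(channels))
    if p_s is None:
        return arimoto_blahut(joint, tol_bits=tol_bits).cc_bits
    return mutual_information(np.asarray(p_s, dtype=float), joint)


def coefficient_of_variation(
    ensemble: TrajectoryEnsemble, species: str, t: float
) -> float:
    """SD / mean of one species across realizations at time ``t``;
    NaN where the mean is zero."""
    x = ensemble.at(species, t).astype(float)
    m = x.mean()
    if m == 0.0:
        return float("nan")
    return float(x.std(ddof=1) / m)
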