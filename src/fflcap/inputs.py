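"""Pathway input dynamics: cytoplasmic ppERK as a prescribed transient.

The decoding section of the MAPK/ERK pathway is driven by doubly
phosphorylated cytoplasmic ERK, whose time course after a growth-factor
pulse is a difference of two saturating exponentials,

    ppERK_cyt(t) = L * [k2*(exp(-t/T2) - 1) - k1*(exp(-t/T1) - 1)],

with amplitude rates k1 > k2 > 0 (m/min), time constants T1, T2 (min) and
a dimensionless scale L that acts as the stimulus-intensity axis of every
channel-capacity sweep.  The trace is 0 at t=0, non-negative for all t,
and tends to L*(k1 - k2) as t -> infinity.

Stochastically the same input is realized by a pair of time-inhomogeneous
zero-/first-order reactions whose hazards are the positive and negative
parts of the derivative of the trace:

    0 -> X   at rate (k1*L/T1) * exp(-t/T1)
    X -> 0   at rate (k2*L/T2) * exp(-t/T2)

so that the ensemble mean of the jump process reproduces the deterministic
trace.  The printed degradation hazard does not depend on the current
count, so it is clamped to zero whenever the count is zero to keep the
state non-negative (the bias is negligible: the deterministic trace is
strictly positive wherever the hazard is appreciable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["InputSpec", "standard_inputs", "l_sweep"]


@dataclass(frozen=True)
class InputSpec:
    """Shape parameters of one ppERK_cyt transient.

    Parameters
    ----------
    k1, k2 : float
        Amplitude rates (m/min); must satisfy k1 > k2 > 0 so the trace
        stays non-negative.
    T1, T2 : float
        Time constants (min), both positive.
    L : float
        Dimensionless scale factor (stimulus intensity), positive.
    label : str
        Identifier; "I1", "I2", "I3" for the standard parameter sets.
    """

    k1: float
    k2: float
    T1: float
    T2: float
    L: float = 100.0
    label: str = "custom"

    def __post_init__(self) -> None:
        if not (self.k1 > self.k2 > 0.0):
            raise ValueError(
                f"input requires k1 > k2 > 0 (got k1={self.k1}, k2={self.k2}); "
                "otherwise ppERK_cyt(t) would go negative"
            )
        if self.T1 <= 0.0 or self.T2 <= 0.0:
            raise ValueError("time constants T1, T2 must be positive")
        # k1 > k2 keeps the asymptote positive but not the early transient:
        # the initial slope is k1/T1 - k2/T2, and requiring it non-negative
        # (true of all three standard parameter sets) guarantees the trace
        # never dips below zero
        if self.k1 / self.T1 < self.k2 / self.T2:
            raise ValueError(
                "input requires k1/T1 >= k2/T2 so the trace starts non-negative"
            )
        if self.L <= 0.0:
            raise ValueError("scale factor L must be positive")

    def with_scale(self, L: float) -> "InputSpec":
        """Same shape at a different stimulus scale."""
        return replace(self, L=L)

    @property
    def amplitude(self) -> float:
        """Asymptotic input level A_N = L*(k1 - k2) (molecule counts)."""
        return self.L * (self.k1 - self.k2)

    # -- deterministic trace -------------------------------------------------

    def eval(self, t):
        """Input level at time ``t`` (min); scalar or array, vectorized."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0.0):
            raise ValueError("time must be non-negative")
        out = self.L * (
            self.k2 * (np.exp(-t / self.T2) - 1.0)
            - self.k1 * (np.exp(-t / self.T1) - 1.0)
        )
        return out if out.ndim else float(out)

    def deriv(self, t):
        """Time derivative of the trace (production minus degradation hazard)."""
        p, d = self.hazards(t)
        return p - d

    def trace_csv(self, path, t_end: float = 200.0, dt: float = 1.0) -> None:
        """Write the deterministic trace as two-column CSV (time_min, level)."""
        t = np.arange(0.0, t_end + 0.5 * dt, dt)
        level = self.eval(t)
        with open(path, "w") as f:
            f.write("time_min,level\n")
            for ti, li in zip(t, level):
                f.write(f"{ti:.6g},{li:.10g}\n")

    # -- stochastic hazards --------------------------------------------------

    def hazards(self, t):
        """Production and degradation hazards (events/min) at time ``t``.

        Returns the pair ``(k1*L/T1 * exp(-t/T1), k2*L/T2 * exp(-t/T2))``;
        both are strictly decreasing in t.  The state-dependent clamp of the
        degradation hazard at count zero lives in the simulation engine.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0.0):
            raise ValueError("time must be non-negative")
        prod = (self.k1 * self.L / self.T1) * np.exp(-t / self.T1)
        deg = (self.k2 * self.L / self.T2) * np.exp(-t / self.T2)
        if prod.ndim:
            return prod, deg
        return float(prod), float(deg)


#: Published parameter sets for the three growth-factor doses.
_STANDARD = {
    "I1": dict(k1=2.19, k2=1.97, T1=3.16, T2=8.68),
    "I2": dict(k1=1.23, k2=0.949, T1=1.0, T2=3.69),
    "I3": dict(k1=0.257, k2=0.101, T1=9.68, T2=6.3),
}


def standard_inputs(L: float = 100.0) -> dict[str, InputSpec]:
    """The three standard input shapes I1, I2, I3 at scale ``L``.

    The sets correspond to the phenomenological ppERK_cyt fits for
    0.1, 1 and 10 nM EGF doses.
    """
    return {
        name: InputSpec(L=L, label=name, **params)
        for name, params in _STANDARD.items()
    }


def l_sweep(lo: float = 10.0, hi: float = 120.0, step: float = 10.0) -> np.ndarray:
    """Ordered stimulus scales; default 10, 20, ..., 120 (12 levels)."""
    if lo <= 0.0 or step <= 0.0 or hi < lo:
        raise ValueError("need lo > 0, step > 0, hi >= lo")
    levels = np.arange(lo, hi + 0.5 * step, step, dtype=float)
    if levels.size == 0:
        raise ValueError("empty sweep")
    return levels
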