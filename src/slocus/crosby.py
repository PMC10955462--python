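"""Deterministic recursion of S-locus genotype frequencies (Crosby's model).

The S-locus of *Primula* is hemizygous: thrums carry one copy (S/0), pins
none (0/0), and homostyles carry one (S*/0) or two (S*/S*) copies of a
haplotype whose style-length/self-incompatibility gene is disrupted.  This
module iterates the classic deterministic recursion for the four genotype
frequencies (p, q, r, s) under viability selection against S*/S* offspring.

Cross model
-----------
Pollen is non-limiting and anther height determines which pollen pool a
stigma receives:

* Pin mothers self at rate ``sigma_pin`` (offspring 0/0); the remainder are
  fertilised by the high-anther pollen pool (thrums and homostyles, export
  proportional to genotype frequency).  The pin ovule allele is always 0.
* Thrum mothers are self-incompatible and receive only pin pollen (allele
  0); offspring segregate 1/2 S/0 : 1/2 0/0.  With no pins present thrums
  leave no offspring.
* Homostyle mothers self at rate ``sigma_hom`` (default 1: anthers and
  stigma touch); the remainder take high-anther pool pollen.  S/S* products
  of thrum pollen on homostyle ovules fall outside the tracked state space
  and are dropped before renormalisation.

Viability selection multiplies the S*/S* offspring class by ``v`` before
frequencies are renormalised each generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "PopulationState",
    "ModelParams",
    "TrajectoryTable",
    "DegeneratePopulationError",
    "gamete_distribution",
    "step",
    "trajectory",
    "find_equilibrium",
    "expected_frequency_grid",
    "DEFAULT_INITIAL_STATE",
    "DEFAULT_V_GRID",
    "DEFAULT_GENERATIONS",
]

#: Tracked S-locus genotypes, in (p, q, r, s) order.
GENOTYPES = ("0/0", "S/0", "S*/0", "S*/S*")

_SUM_TOL = 1e-9


class DegeneratePopulationError(ValueError):
    """Raised when no compatible matings can produce any offspring."""


@dataclass(frozen=True)
class PopulationState:
    """Frequencies of the four S-locus genotypes in one generation.

    Attributes
    ----------
    p, q, r, s:
        Frequencies of 0/0 (pin), S/0 (thrum), S*/0 and S*/S* (homostyles).
        Must be non-negative and sum to 1 within 1e-9.
    generation:
        Non-negative generation index.
    """

    p: float
    q: float
    r: float
    s: float
    generation: int = 0

    def __post_init__(self) -> None:
        freqs = (self.p, self.q, self.r, self.s)
        for name, x in zip("pqrs", freqs):
            if not (-_SUM_TOL <= x <= 1 + _SUM_TOL):
                raise ValueError(f"frequency {name}={x!r} outside [0, 1]")
        total = sum(freqs)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"frequencies sum to {total!r}, expected 1")
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.q, self.r, self.s], dtype=float)

    @classmethod
    def from_array(cls, freqs, generation: int = 0) -> "PopulationState":
        freqs = np.asarray(freqs, dtype=float)
        freqs = np.where(np.abs(freqs) < 1e-15, 0.0, freqs)
        return cls(*freqs.tolist(), generation=generation)

    def is_interior(self) -> bool:
        return min(self.p, self.q, self.r, self.s) > 0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the genotype-frequency recursion.

    Attributes
    ----------
    v:
        Viability of S*/S* offspring relative to all other genotypes, in
        (0, 1].  ``v=0.65`` corresponds to a 35% viability deficit.
    sigma_pin:
        Selfing rate of pins (default 0.10; setting it to 0 does not change
        the qualitative outcomes).
    sigma_hom:
        Selfing rate of homostyles (default 1.0).
    tol:
        L-infinity convergence tolerance for equilibrium search.
    max_gens:
        Iteration cap for equilibrium search.
    """

    v: float = 1.0
    sigma_pin: float = 0.10
    sigma_hom: float = 1.0
    tol: float = 1e-10
    max_gens: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.v <= 1):
            raise ValueError("v must be in (0, 1]")
        for name in ("sigma_pin", "sigma_hom"):
            x = getattr(self, name)
            if not (0 <= x <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tol <= 0 or self.max_gens < 1:
            raise ValueError("tol must be > 0 and max_gens >= 1")


#: Documented conventional starting state: a distylous population into which
#: a single-copy homostyle haplotype has just been introduced at 1%.
DEFAULT_INITIAL_STATE = PopulationState(p=0.495, q=0.495, r=0.01, s=0.0)

DEFAULT_V_GRID = (1.0, 0.9, 0.8, 0.7, 0.65, 0.6, 0.5)
DEFAULT_GENERATIONS = (10, 20, 30, 40)


def gamete_distribution(genotype: str) -> dict[str, float]:
    """Mendelian gamete frequencies of a (possibly hemizygous) genotype.

    The null haplotype "0" segregates like an allele: a hemizygote such as
    S*/0 transmits the S-bearing chromosome to half its gametes.
    """
    table = {
        "0/0": {"0": 1.0},
        "S/0": {"S": 0.5, "0": 0.5},
        "S*/0": {"S*": 0.5, "0": 0.5},
        "S*/S*": {"S*": 1.0},
    }
    try:
        return dict(table[genotype])
    except KeyError:
        raise ValueError(f"unknown genotype {genotype!r}") from None


def step(state: PopulationState, params: ModelParams) -> PopulationState:
    """Advance the genotype frequencies by one generation."""
    p, q, r, s = state.p, state.q, state.r, state.s
    # offspring weights in GENOTYPES order
    w = np.zeros(4)

    # High-anther pollen pool: thrums and homostyles export pollen in
    # proportion to their genotype frequency.
    pool = {
        "S": 0.5 * q,
        "S*": 0.5 * r + s,
        "0": 0.5 * q + 0.5 * r,
    }
    pool_total = q + r + s
    if pool_total > 0:
        pollen = {a: x / pool_total for a, x in pool.items()}
    else:
        pollen = None

    # Pin mothers: selfed fraction breeds true; outcrossed ovules always
    # carry allele 0, so the offspring genotype is set by the pollen allele.
    w[0] += p * params.sigma_pin
    if pollen is not None:
        out = p * (1 - params.sigma_pin)
        w[1] += out * pollen["S"]
        w[2] += out * pollen["S*"]
        w[0] += out * pollen["0"]

    # Thrum mothers: self-incompatible, pin pollen (allele 0) only.
    if p > 0:
        w[1] += 0.5 * q
        w[0] += 0.5 * q

    # Homostyle mothers.
    self_r = r * params.sigma_hom
    w[0] += 0.25 * self_r
    w[2] += 0.50 * self_r
    w[3] += 0.25 * self_r
    w[3] += s * params.sigma_hom
    if pollen is not None and params.sigma_hom < 1:
        out_r = r * (1 - params.sigma_hom)
        # ovules of S*/0: half S*, half 0; S (pollen) x S* (ovule) products
        # are S/S*, outside the state space, and are dropped.
        w[3] += out_r * 0.5 * pollen["S*"]
        w[2] += out_r * 0.5 * pollen["0"]
        w[1] += out_r * 0.5 * pollen["S"]
        w[2] += out_r * 0.5 * pollen["S*"]
        w[0] += out_r * 0.5 * pollen["0"]
        out_s = s * (1 - params.sigma_hom)
        w[3] += out_s * pollen["S*"]
        w[2] += out_s * pollen["0"]

    # Viability selection on S*/S* offspring, then renormalise.
    w[3] *= params.v
    total = w.sum()
    if total <= 0:
        raise DegeneratePopulationError(
            "no compatible matings produce offspring from this state"
        )
    return PopulationState.from_array(w / total, generation=state.generation + 1)


@dataclass
class TrajectoryTable:
    """An ordered sequence of population states with the generating params."""

    states: list[PopulationState]
    params: ModelParams

    def __post_init__(self) -> None:
        gens = [st.generation for st in self.states]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generation indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]

    def at_generation(self, generation: int) -> PopulationState:
        for st in self.states:
            if st.generation == generation:
                return st
        raise KeyError(f"generation {generation} not in trajectory")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [st.generation for st in self.states],
                "p": [st.p for st in self.states],
                "q": [st.q for st in self.states],
                "r": [st.r for st in self.states],
                "s": [st.s for st in self.states],
            }
        )


def trajectory(
    state0: PopulationState, params: ModelParams, n_gens: int
) -> TrajectoryTable:
    """Iterate :func:`step` from ``state0`` for ``n_gens`` generations."""
    if n_gens < 0:
        raise ValueError("n_gens must be >= 0")
    states = [state0]
    st = state0
    for _ in range(n_gens):
        st = step(st, params)
        states.append(st)
    return TrajectoryTable(states=states, params=params)


def find_equilibrium(
    state0: PopulationState, params: ModelParams
) -> tuple[PopulationState, bool]:
    """Iterate to a fixed point of the recursion.

    Returns the final state and whether the L-infinity change between
    consecutive generations fell below ``params.tol`` within
    ``params.max_gens`` iterations.
    """
    st = state0
    for _ in range(params.max_gens):
        nxt = step(st, params)
        if np.max(np.abs(nxt.as_array() - st.as_array())) < params.tol:
            return nxt, True
        st = nxt
    return st, False


def expected_frequency_grid(
    state0: PopulationState = DEFAULT_INITIAL_STATE,
    v_values=DEFAULT_V_GRID,
    generations=DEFAULT_GENERATIONS,
    base: ModelParams | None = None,
) -> pd.DataFrame:
    """Expected genotype frequencies over a (viability x generation) grid.

    One trajectory is run per viability value and sampled at the requested
    generations.  Returns a DataFrame with columns
    ``v, generation, p, q, r, s``.
    """
    v_values = list(v_values)
    generations = sorted(generations)
    if not v_values:
        raise ValueError("v_values must be non-empty")
    if base is None:
        base = ModelParams()
    rows = []
    for v in v_values:
        params = ModelParams(
            v=v,
            sigma_pin=base.sigma_pin,
            sigma_hom=base.sigma_hom,
            tol=base.tol,
            max_gens=base.max_gens,
        )
        traj = trajectory(state0, params, max(generations) if generations else 0)
        for g in generations:
            st = traj.at_generation(g)
            rows.append(
                {"v": v, "generation": g, "p": st.p, "q": st.q, "r": st.r, "s": st.s}
            )
    return pd.DataFrame(rows)
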