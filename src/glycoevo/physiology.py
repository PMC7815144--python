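"""Cell physiology: growth, health, expression costs, division and mutation.

Glycolysis is coupled to fitness through the ATPase flux ``v_atp``: it first
pays the maintenance cost ``v_atp,c = v_atp,e + v_atp,m`` (enzyme expression
plus general maintenance) and the remainder, the growth flux ``v_atp,g``, is
invested in new cell volume.  A cell whose growth flux is negative draws on
internal reserves, modelled by a health variable ``H``; it dies when H
reaches 0 and resumes growth only after H has recovered to its individual
maximum ``H_max``.

Two calibration constants anchor the model to yeast physiology:

* ``u_g`` (per mM/min): chosen so a reference cell in the balanced state at
  2 mM glucose doubles its volume in the generation time ``tau_g``;
* ``u_d`` (per mM/min): chosen so a reference cell trapped in the imbalanced
  state dies (H: 1 -> 0) in the death time ``tau_d``.  ``u_d`` carries the
  literal sign of its defining relation (it is negative because the
  reference imbalanced growth flux is negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from glycoevo.kinetics import Genotype, KineticParameters, MetaboliteState

__all__ = [
    "CostModel",
    "PhysiologyParameters",
    "Cell",
    "expression_cost",
    "normalize_cost",
    "growth_flux",
    "volume_rate",
    "health_rate",
    "divide_cell",
    "mutate_genotype",
    "REFERENCE_GENOTYPE",
]

#: Reference genotype: the published parameterisation of the source core
#: glycolysis model (vmax_up, vmax_lo in mM/min; k_atp, k_p in 1/min).
REFERENCE_GENOTYPE = Genotype(10.0, 10.0, 10.0, 0.3)


@dataclass(frozen=True)
class CostModel:
    """Expression-cost function mapping a genotype to an ATP flux (mM/min).

    Two variants are supported:

    * ``power_sum`` (default): k_e * sum_x (w_x x)^n — each rate constant
      contributes a separate power-law term;
    * ``power_of_sum``: k_e * (sum_x w_x x)^n — the alternative form in
      which the weighted sum is raised to the power.

    Rate constants ``k_atp`` and ``k_p`` are multiplied by the unit
    concentration ``c_u`` = 1 mM for dimensional consistency.  ``k_e`` is a
    normalising factor fixed by :func:`normalize_cost` so the reference
    genotype costs exactly ``vatp_e_ref``.  Both variants coincide at n=1.
    """

    variant: str = "power_sum"
    w_up: float = 1.0
    w_lo: float = 1.0
    w_atp: float = 1.0
    w_p: float = 1.0
    n: float = 4.0
    c_u: float = 1.0
    vatp_e_ref: float = 5.0
    k_e: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("power_sum", "power_of_sum"):
            raise ValueError("variant must be 'power_sum' or 'power_of_sum'")

    @property
    def normalized(self) -> bool:
        return self.k_e is not None

    def _raw(self, g: Genotype) -> float:
        terms = (
            self.w_up * g.vmax_up,
            self.w_lo * g.vmax_lo,
            self.w_atp * self.c_u * g.k_atp,
            self.w_p * self.c_u * g.k_p,
        )
        if self.variant == "power_sum":
            return sum(t**self.n for t in terms)
        return sum(terms) ** self.n


def normalize_cost(c: CostModel, reference: Genotype = REFERENCE_GENOTYPE) -> CostModel:
    """Return a copy of ``c`` with k_e set so the reference genotype costs
    ``c.vatp_e_ref`` exactly."""
    raw = c._raw(reference)
    if raw <= 0:
        raise ValueError("reference genotype has zero raw cost; cannot normalize")
    return replace(c, k_e=c.vatp_e_ref / raw)


def expression_cost(g: Genotype, c: CostModel) -> float:
    """Expression cost v_atp,e (mM/min) of genotype ``g`` under model ``c``."""
    if not c.normalized:
        raise ValueError("CostModel must be normalized first (see normalize_cost)")
    return c.k_e * c._raw(g)


@dataclass(frozen=True)
class PhysiologyParameters:
    """Growth/health coupling constants.

    ``vatp_ref_balanced`` and ``vatp_ref_imbalanced`` are the ATPase fluxes
    of the reference genotype in the balanced and imbalanced state at
    constant 2 mM glucose; together with ``tau_g`` (generation time) and
    ``tau_d`` (death time in the imbalanced state) they fix ``u_g`` and
    ``u_d``.  ``V_c`` is the standard cytosol volume of a cell.
    """

    vatp_m: float = 0.0
    tau_g: float = 90.0
    tau_d: float = 420.0
    vatp_ref_balanced: float = 12.7
    vatp_ref_imbalanced: float = 0.46
    vatp_e_ref: float = 5.0
    V_c: float = 3.35e-15
    H_min: float = 0.0
    u_g: float = field(init=False)
    u_d: float = field(init=False)

    def __post_init__(self) -> None:
        vgb = self.vatp_ref_balanced - self.vatp_e_ref - self.vatp_m
        vgi = self.vatp_ref_imbalanced - self.vatp_e_ref - self.vatp_m
        if vgb <= 0:
            raise ValueError("reference balanced growth flux must be positive")
        if vgi >= 0:
            raise ValueError("reference imbalanced growth flux must be negative")
        object.__setattr__(self, "u_g", math.log(2.0) / (self.tau_g * vgb))
        object.__setattr__(self, "u_d", 1.0 / (self.tau_d * vgi))

    @property
    def vatp_g_ref_balanced(self) -> float:
        return self.vatp_ref_balanced - self.vatp_e_ref - self.vatp_m

    @property
    def vatp_g_ref_imbalanced(self) -> float:
        return self.vatp_ref_imbalanced - self.vatp_e_ref - self.vatp_m


def growth_flux(v_atp: float, vatp_e: float, p: PhysiologyParameters) -> float:
    """Growth flux v_atp,g = v_atp - (v_atp,e + v_atp,m); may be negative."""
    return v_atp - (vatp_e + p.vatp_m)


def volume_rate(
    v_atp_g: float, H: float, H_max: float, p: PhysiologyParameters
) -> float:
    """Fractional volume growth rate V'/V (1/min).

    Growth requires full health and a positive growth flux:
    V'/V = u_g * v_atp,g if H = H_max and v_atp,g > 0, else 0.
    """
    if H >= H_max and v_atp_g > 0:
        return p.u_g * v_atp_g
    return 0.0


def health_rate(
    v_atp_g: float, H: float, H_max: float, p: PhysiologyParameters
) -> float:
    """Health dynamics H' (1/min).

    H' = -u_d * v_atp,g           if v_atp,g <= 0   (deterioration; u_d < 0)
       =  u_g * v_atp,g           if v_atp,g > 0 and H < H_max   (recovery)
       =  0                       if v_atp,g > 0 and H = H_max
    """
    if v_atp_g <= 0:
        return -p.u_d * v_atp_g
    if H < H_max:
        return p.u_g * v_atp_g
    return 0.0


@dataclass
class Cell:
    """A single cell: genotype, metabolite state, volume, health.

    ``vatp_e`` caches the expression cost of the genotype (constant between
    mutations).  ``H_max`` is the cell's individual maximum health, drawn
    uniformly from [0.9, 1.1] at birth to desynchronise clonal populations.
    """

    genotype: Genotype
    state: MetaboliteState
    V: float
    H: float
    H_max: float
    vatp_e: float

    def validate(self, k: KineticParameters) -> None:
        if self.V <= 0:
            raise ValueError("cell volume must be positive")
        if not 0 <= self.H <= self.H_max:
            raise ValueError("H must lie in [0, H_max]")
        self.state.validate(k)


def divide_cell(
    c: Cell, rng: np.random.Generator, p: PhysiologyParameters
) -> tuple[Cell, Cell]:
    """Split a cell of volume >= 2 V_c into two daughters.

    One daughter (chosen by a fair coin) receives a fresh random volume
    U(0.5 V_c, 1.5 V_c); the other receives the complement so total volume
    is conserved.  Each daughter draws a fresh H_max ~ U(0.9, 1.1) and
    starts at full health.  Metabolite concentrations and the genotype are
    copied unchanged — division without mutation is a simple physical split.
    """
    if c.V < 2.0 * p.V_c:
        raise ValueError("cell volume below division threshold 2*V_c")
    v_random = rng.uniform(0.5 * p.V_c, 1.5 * p.V_c)
    volumes = [v_random, c.V - v_random]
    if rng.random() < 0.5:
        volumes.reverse()
    daughters = []
    for v in volumes:
        h_max = rng.uniform(0.9, 1.1)
        daughters.append(
            Cell(
                genotype=c.genotype,
                state=MetaboliteState(c.state.FBP, c.state.ATP, c.state.Pi),
                V=v,
                H=h_max,
                H_max=h_max,
                vatp_e=c.vatp_e,
            )
        )
    return daughters[0], daughters[1]


def mutate_genotype(
    g: Genotype, mu: float, sigma: float, rng: np.random.Generator
) -> Genotype:
    """Mutate each rate constant independently with probability ``mu``.

    A mutated value is x_m = x_p * exp(X), X ~ N(0, sigma^2): a multiplicative
    random walk whose median leaves the parental value unchanged.
    """
    if not 0 <= mu <= 1:
        raise ValueError("mu must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    values = list(g.as_tuple())
    for i in range(4):
        if rng.random() < mu:
            values[i] = values[i] * math.exp(rng.normal(0.0, sigma))
    return Genotype(*values)
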