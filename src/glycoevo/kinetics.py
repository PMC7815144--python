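"""Reaction kinetics of the core glycolysis pathway.

The pathway lumps glycolysis into four reactions acting on three cytosolic
metabolite pools — FBP (fructose-1,6-bisphosphate), ATP and inorganic
phosphate P_i:

* **upper glycolysis** (UG): glucose + 2 ATP -> FBP, irreversible
  two-substrate Michaelis-Menten kinetics with allosteric ATP inhibition
  (phosphofructokinase is inhibited by high ATP);
* **lower glycolysis** (LG): FBP + 2 ADP + 2 P_i -> 4 ATP (net +2),
  irreversible three-substrate Michaelis-Menten kinetics;
* **ATPase**: first-order ATP demand representing all cellular consumption;
* **phosphate transport**: reversible exchange of P_i between the vacuole
  and the cytosol, driven by the concentration difference.  The vacuolar
  phosphate level is buffered by the polyphosphate store and declines as
  phosphate accumulates in the cytosol (bound in FBP and ATP).

ADP is never stored as state: the adenosine pool ``a_tot = [ATP] + [ADP]``
is conserved, so ``[ADP] = a_tot - [ATP]``.  Growth of the cell dilutes all
cytosolic metabolites at the fractional volume growth rate ``V'/V``.

All concentrations are mM, all times minutes, all fluxes mM/min.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "KineticParameters",
    "Genotype",
    "MetaboliteState",
    "upper_glycolysis_rate",
    "lower_glycolysis_rate",
    "atpase_rate",
    "vacuole_phosphate",
    "phosphate_transport_rate",
    "metabolite_derivatives",
]


@dataclass(frozen=True)
class KineticParameters:
    """Non-evolvable kinetic constants of the pathway.

    Defaults are the standard parameterisation for yeast (the ``table1``
    preset): Michaelis constants of UG and LG, the ATP-inhibition constant
    of UG, the conserved adenosine pool, and the vacuolar phosphate buffer.

    Attributes
    ----------
    KM_glc, KM_atp : float
        Michaelis constants (mM) for glucose and ATP in UG.
    Ki_atp : float
        Inhibitor constant (mM) for ATP in UG.
    a_tot : float
        Total ATP + ADP concentration (mM), conserved.
    KM_fbp, KM_adp, KM_p : float
        Michaelis constants (mM) for FBP, ADP and P_i in LG.
    Pi_vac_max : float
        Vacuolar P_i concentration (mM) when no phosphate has been imported
        into the cytosol.
    K_vac : float
        Total cytosolic phosphate (mM) that halves the vacuolar P_i level;
        sets the effective size of the vacuolar phosphate store.
    m : float
        Steepness of vacuolar phosphate depletion (dimensionless, > 0).
    """

    KM_glc: float = 0.1
    KM_atp: float = 0.1
    Ki_atp: float = 3.0
    a_tot: float = 5.0
    KM_fbp: float = 1.0
    KM_adp: float = 0.1
    KM_p: float = 2.0
    Pi_vac_max: float = 10.0
    K_vac: float = 250.0
    m: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "KM_glc", "KM_atp", "Ki_atp", "a_tot", "KM_fbp",
            "KM_adp", "KM_p", "Pi_vac_max", "K_vac", "m",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Genotype:
    """The four evolvable rate constants, proxies for enzyme expression levels.

    ``vmax_up`` and ``vmax_lo`` (mM/min) are the maximal UG and LG rates;
    ``k_atp`` and ``k_p`` (1/min) are the first-order constants of the ATPase
    and phosphate-transport reactions.
    """

    vmax_up: float
    vmax_lo: float
    k_atp: float
    k_p: float

    def __post_init__(self) -> None:
        for name in ("vmax_up", "vmax_lo", "k_atp", "k_p"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.vmax_up, self.vmax_lo, self.k_atp, self.k_p)


@dataclass
class MetaboliteState:
    """Cytosolic metabolite concentrations (mM) of a single cell."""

    FBP: float
    ATP: float
    Pi: float

    def validate(self, k: KineticParameters) -> None:
        if self.FBP < 0 or self.Pi < 0:
            raise ValueError("FBP and Pi must be non-negative")
        if not 0 <= self.ATP <= k.a_tot:
            raise ValueError(f"ATP must lie in [0, a_tot={k.a_tot}]")

    def adp(self, k: KineticParameters) -> float:
        """[ADP] from the conserved adenosine pool."""
        return k.a_tot - self.ATP

    def p_tot(self) -> float:
        """Total phosphate imported into the cytosol: P_i + 2 FBP + ATP."""
        return self.Pi + 2.0 * self.FBP + self.ATP


def upper_glycolysis_rate(
    s: MetaboliteState, glc: float, g: Genotype, k: KineticParameters
) -> float:
    """UG flux (mM/min): two-substrate MM kinetics with ATP inhibition.

    v_up = vmax_up [Glc][ATP] / ((KM_glc+[Glc]) (KM_atp + [ATP](1+[ATP]/Ki_atp)))

    The inhibition term makes v_up unimodal in ATP with an interior maximum
    at [ATP] = sqrt(KM_atp * Ki_atp).
    """
    if glc < 0:
        raise ValueError("glucose concentration must be non-negative")
    s.validate(k)
    return (
        g.vmax_up
        * glc
        * s.ATP
        / ((k.KM_glc + glc) * (k.KM_atp + s.ATP * (1.0 + s.ATP / k.Ki_atp)))
    )


def lower_glycolysis_rate(
    s: MetaboliteState, g: Genotype, k: KineticParameters
) -> float:
    """LG flux (mM/min): three-substrate MM kinetics in FBP, ADP and P_i."""
    s.validate(k)
    adp = s.adp(k)
    return (
        g.vmax_lo
        * s.FBP
        * adp
        * s.Pi
        / ((k.KM_fbp + s.FBP) * (k.KM_adp + adp) * (k.KM_p + s.Pi))
    )


def atpase_rate(s: MetaboliteState, g: Genotype) -> float:
    """ATP demand flux (mM/min): first-order, v_atp = k_atp [ATP]."""
    if s.ATP < 0:
        raise ValueError("ATP must be non-negative")
    return g.k_atp * s.ATP


def vacuole_phosphate(p_tot: float, k: KineticParameters) -> float:
    """Buffered vacuolar P_i concentration (mM) as a function of P_tot.

    [P_i]_vac = Pi_vac_max / (1 + (P_tot/K_vac)^m); strictly decreasing in
    P_tot, equal to half its maximum at P_tot = K_vac.
    """
    if p_tot < 0:
        raise ValueError("P_tot must be non-negative")
    return k.Pi_vac_max / (1.0 + (p_tot / k.K_vac) ** k.m)


def phosphate_transport_rate(
    s: MetaboliteState, g: Genotype, k: KineticParameters
) -> float:
    """Vacuole<->cytosol phosphate flux (mM/min), positive into the cytosol.

    v_p = k_p ([P_i]_vac - [P_i]) with the vacuolar level evaluated at the
    current total imported phosphate P_tot = P_i + 2 FBP + ATP.
    """
    s.validate(k)
    return g.k_p * (vacuole_phosphate(s.p_tot(), k) - s.Pi)


def metabolite_derivatives(
    s: MetaboliteState,
    glc: float,
    frac_growth: float,
    g: Genotype,
    k: KineticParameters,
) -> tuple[float, float, float]:
    """Right-hand side (d[FBP], d[ATP], d[P_i])/dt of the metabolite ODEs.

    [FBP]' = v_up - v_lo            - [FBP] V'/V
    [ATP]' = -2 v_up + 4 v_lo - v_atp - [ATP] V'/V
    [P_i]' = -2 v_lo + v_atp + v_p    - [P_i] V'/V

    ``frac_growth`` is the fractional volume growth rate V'/V (1/min); the
    dilution terms keep metabolite amounts consistent as the cell grows.
    A useful algebraic identity of these equations: at any state,
    dP_tot/dt = v_p - P_tot * V'/V.
    """
    if frac_growth < 0:
        raise ValueError("frac_growth must be non-negative")
    v_up = upper_glycolysis_rate(s, glc, g, k)
    v_lo = lower_glycolysis_rate(s, g, k)
    v_atp = atpase_rate(s, g)
    v_p = phosphate_transport_rate(s, g, k)
    d_fbp = v_up - v_lo - s.FBP * frac_growth
    d_atp = -2.0 * v_up + 4.0 * v_lo - v_atp - s.ATP * frac_growth
    d_pi = -2.0 * v_lo + v_atp + v_p - s.Pi * frac_growth
    return (d_fbp, d_atp, d_pi)
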