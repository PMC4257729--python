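"""Priority-ladder energy allocation.

Each timestep, sources of energy are assigned to demands in strict priority
order.  Sources: dietary intake is used completely before *extra* fat and
fat-free mass (mass beyond the indicated trajectory) are tapped, and only
when those are exhausted may *essential* mass (the mass composing the
indicated trajectory) be catabolized for survival — and then only for
maintenance.  Demands: maintenance is served first, then deposition of
essential FM/FFM (normal growth and catch-up), and only then may surplus
intake deposit extra mass.

Deposition and consumption of extra mass split between FM and FFM by the
partition fraction p_FFM; all mass <-> energy conversions use the exact
cumulative energy curves so that each step conserves energy to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .composition import (CompositionParams, IndicatedState, ffm_energy_delta,
                          solve_consume, solve_deposit)
from .demand import MetabolicParams
from .errors import ParameterError

_EPS = 1e-12


@dataclass(frozen=True)
class StorePartition:
    """Split of each compartment into extra (beyond trajectory) and essential
    (composing the trajectory) mass."""

    extra_fm: float
    extra_ffm: float
    essential_fm: float
    essential_ffm: float

    @property
    def fm(self) -> float:
        return self.extra_fm + self.essential_fm

    @property
    def ffm(self) -> float:
        return self.extra_ffm + self.essential_ffm


def classify_stores(fm: float, ffm: float, indicated: IndicatedState) -> StorePartition:
    """Partition current masses against the indicated trajectory."""
    if fm < 0 or ffm < 0:
        raise ParameterError("masses must be non-negative")
    return StorePartition(
        extra_fm=max(0.0, fm - indicated.fm_star),
        extra_ffm=max(0.0, ffm - indicated.ffm_star),
        essential_fm=min(fm, indicated.fm_star),
        essential_ffm=min(ffm, indicated.ffm_star),
    )


@dataclass
class AllocationResult:
    """Resolved energy flows (MJ per step) and net mass changes (kg per step).

    ``flows`` maps (source, demand) pairs over sources
    {ei, extra_fm, extra_ffm, essential_fm, essential_ffm} and demands
    {maintenance, essential_fm_dep, essential_ffm_dep, extra_dep}.
    """

    flows: dict[tuple[str, str], float] = field(default_factory=dict)
    net_dfm: float = 0.0
    net_dffm: float = 0.0
    maintenance_served: float = 0.0
    unmet_maintenance: float = 0.0
    growth_fm_funded: float = 0.0
    growth_ffm_funded: float = 0.0
    growth_demanded: float = 0.0
    catabolized_energy: float = 0.0
    stored_energy: float = 0.0
    deposition_losses: float = 0.0

    @property
    def growth_fraction(self) -> float:
        """Share of the essential-deposition energy demand actually funded."""
        if self.growth_demanded <= _EPS:
            return 1.0
        return min(1.0, (self.growth_fm_funded + self.growth_ffm_funded)
                   / self.growth_demanded)

    def _add_flow(self, source: str, demand: str, energy: float) -> None:
        if energy > _EPS:
            key = (source, demand)
            self.flows[key] = self.flows.get(key, 0.0) + energy


class _Ledger:
    """Mutable bookkeeping while the ladder is resolved."""

    def __init__(self, fm: float, ffm: float, stores: StorePartition,
                 p_ffm: float, comp: CompositionParams, met: MetabolicParams):
        self.fm = fm
        self.ffm = ffm
        self.avail = {
            "extra_fm": min(stores.extra_fm, fm),
            "extra_ffm": min(stores.extra_ffm, ffm),
            "essential_fm": max(0.0, fm - stores.extra_fm),
            "essential_ffm": max(0.0, ffm - stores.extra_ffm),
        }
        self.p_ffm = p_ffm
        self.comp = comp
        self.met = met
        self.result = AllocationResult()

    def draw(self, tier: str, energy_needed: float, demand: str) -> float:
        """Catabolize mass from an extra/essential tier; returns energy obtained."""
        res = self.result
        obtained = 0.0
        fm_key, ffm_key = f"{tier}_fm", f"{tier}_ffm"
        while energy_needed - obtained > _EPS:
            a_fm, a_ffm = self.avail[fm_key], self.avail[ffm_key]
            if a_fm <= _EPS and a_ffm <= _EPS:
                break
            if a_ffm <= _EPS:
                p = 0.0
            elif a_fm <= _EPS:
                p = 1.0
            else:
                p = self.p_ffm
            m = solve_consume(self.ffm, p, energy_needed - obtained, self.comp)
            # cap at the binding compartment, then loop for the remainder
            m_cap = m
            if p > 0.0:
                m_cap = min(m_cap, a_ffm / p)
            if p < 1.0:
                m_cap = min(m_cap, a_fm / (1.0 - p))
            m = min(m, m_cap)
            if m <= _EPS:
                break
            dffm, dfm = p * m, (1.0 - p) * m
            e_ffm = ffm_energy_delta(self.ffm - dffm, self.ffm, self.comp)
            e_fm = dfm * self.comp.rho_fm
            self.ffm -= dffm
            self.fm -= dfm
            self.avail[ffm_key] -= dffm
            self.avail[fm_key] -= dfm
            res.net_dffm -= dffm
            res.net_dfm -= dfm
            res._add_flow(ffm_key, demand, e_ffm)
            res._add_flow(fm_key, demand, e_fm)
            obtained += e_ffm + e_fm
        res.catabolized_energy += obtained
        return obtained

    def deposit_essential(self, energy_fm: float, energy_ffm: float) -> None:
        res = self.result
        comp, met = self.comp, self.met
        if energy_fm > _EPS:
            stored = energy_fm * met.deposition_efficiency_fm
            dfm = stored / comp.rho_fm
            self.fm += dfm
            res.net_dfm += dfm
            res.stored_energy += stored
            res.deposition_losses += energy_fm - stored
        if energy_ffm > _EPS:
            dffm = solve_deposit(self.ffm, 1.0, energy_ffm,
                                 met.deposition_efficiency_ffm,
                                 met.deposition_efficiency_fm, comp)
            stored = ffm_energy_delta(self.ffm, self.ffm + dffm, comp)
            self.ffm += dffm
            res.net_dffm += dffm
            res.stored_energy += stored
            res.deposition_losses += energy_ffm - stored

    def deposit_extra(self, energy: float) -> None:
        res = self.result
        comp, met = self.comp, self.met
        m = solve_deposit(self.ffm, self.p_ffm, energy,
                          met.deposition_efficiency_ffm,
                          met.deposition_efficiency_fm, comp)
        dffm, dfm = self.p_ffm * m, (1.0 - self.p_ffm) * m
        stored = dfm * comp.rho_fm + ffm_energy_delta(self.ffm, self.ffm + dffm, comp)
        self.ffm += dffm
        self.fm += dfm
        res.net_dffm += dffm
        res.net_dfm += dfm
        res.stored_energy += stored
        res.deposition_losses += energy - stored


def allocate(ei: float, maintenance: float, growth_fm: float, growth_ffm: float,
             stores: StorePartition, p_ffm: float, fm: float, ffm: float,
             comp: CompositionParams, met: MetabolicParams) -> AllocationResult:
    """Resolve one step of the priority ladder.

    All arguments are energies in MJ for the step (rates already multiplied
    by the step length) except the masses (kg).  Returns the resolved flows;
    ``unmet_maintenance`` > 0 signals starvation collapse to the caller.
    """
    if ei < 0 or maintenance < 0 or growth_fm < 0 or growth_ffm < 0:
        raise ParameterError("energies must be non-negative")
    if not 0.0 < p_ffm < 1.0:
        raise ParameterError("p_ffm must lie strictly in (0, 1)")
    led = _Ledger(fm, ffm, stores, p_ffm, comp, met)
    res = led.result
    res.growth_demanded = growth_fm + growth_ffm

    # --- maintenance: EI, then extra stores, then essential stores
    from_ei = min(ei, maintenance)
    res._add_flow("ei", "maintenance", from_ei)
    rem_ei = ei - from_ei
    short = maintenance - from_ei
    if short > _EPS:
        short -= led.draw("extra", short, "maintenance")
    if short > _EPS:
        short -= led.draw("essential", short, "maintenance")
    res.maintenance_served = maintenance - max(0.0, short)
    res.unmet_maintenance = max(0.0, short)

    # --- essential deposition: remaining EI, then extra stores
    g_total = growth_fm + growth_ffm
    funded_fm = funded_ffm = 0.0
    if g_total > _EPS and res.unmet_maintenance <= _EPS:
        from_ei_g = min(rem_ei, g_total)
        rem_ei -= from_ei_g
        obtained = from_ei_g
        res._add_flow("ei", "essential_fm_dep", from_ei_g * growth_fm / g_total)
        res._add_flow("ei", "essential_ffm_dep", from_ei_g * growth_ffm / g_total)
        shortfall = g_total - from_ei_g
        if shortfall > _EPS:
            obtained += led.draw("extra", shortfall, "essential_dep")
        funded_fm = obtained * growth_fm / g_total
        funded_ffm = obtained * growth_ffm / g_total
        led.deposit_essential(funded_fm, funded_ffm)
    res.growth_fm_funded = funded_fm
    res.growth_ffm_funded = funded_ffm

    # --- surplus EI deposits extra mass
    if rem_ei > _EPS and res.unmet_maintenance <= _EPS:
        res._add_flow("ei", "extra_dep", rem_ei)
        led.deposit_extra(rem_ei)

    return res


@dataclass(frozen=True)
class CorrectionFlows:
    """Composition-correction exchange for one step (masses in kg, energies MJ)."""

    dfm: float
    dffm: float
    supply_energy: float   # released energy beyond the deposit cost (to the ladder)
    demand_energy: float   # deposit cost beyond the released energy (maintenance demand)
    stored_energy: float
    released_energy: float
    losses: float


def composition_correction(fm: float, ffm: float, fm_indicated: float,
                           tau_days: float, dt: float,
                           comp: CompositionParams, met: MetabolicParams
                           ) -> CorrectionFlows:
    """FM <-> FFM exchange restoring the composition indicated by the current BMI.

    Moves (FM - FM_indicated)/tau per day out of fat at fixed body weight.
    Energy released by the shrinking compartment funds the growing one
    (with deposition efficiency); any surplus or deficit is handed to the
    allocation ladder.  The per-step exchange is capped at a quarter of the
    shrinking compartment to keep the explicit step well behaved.
    """
    if tau_days <= 0:
        raise ParameterError("correction time constant must be positive")
    e = (fm - fm_indicated) / tau_days * dt
    if abs(e) <= _EPS:
        return CorrectionFlows(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    if e > 0:  # fat above indicated: FM -> FFM
        e = min(e, 0.25 * fm)
        released = e * comp.rho_fm
        stored = ffm_energy_delta(ffm, ffm + e, comp)
        cost = stored / met.deposition_efficiency_ffm
        return CorrectionFlows(
            dfm=-e, dffm=+e,
            supply_energy=max(0.0, released - cost),
            demand_energy=max(0.0, cost - released),
            stored_energy=stored, released_energy=released,
            losses=cost - stored,
        )
    e = min(-e, 0.25 * ffm)  # fat below indicated: FFM -> FM
    released = ffm_energy_delta(ffm - e, ffm, comp)
    stored = e * comp.rho_fm
    cost = stored / met.deposition_efficiency_fm
    return CorrectionFlows(
        dfm=+e, dffm=-e,
        supply_energy=max(0.0, released - cost),
        demand_energy=max(0.0, cost - released),
        stored_energy=stored, released_energy=released,
        losses=cost - stored,
    )
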