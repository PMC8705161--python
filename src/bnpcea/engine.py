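"""Monthly Markov cohort engine for the five-state heart-failure model.

The cohort starts in the no-rehospitalization state and each month either
stays put, is rehospitalized (moving one state up, NRH → RH1 → RH2 → RH3),
or dies.  Death combines the state-specific HF mortality with age-banded
background mortality as independent competing risks.  Under BNP guidance the
hospitalization probabilities are scaled by the relative risk; mortality is
untouched, reflecting the evidence that BNP-guided therapy reduces
hospitalization but not death.  Costs accrue per cycle of state occupancy
(or once per admission in event mode) and utilities accrue as QALYs at 1/12
year per cycle, each discounted at its own annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    ALIVE_STATES,
    Arm,
    HealthState,
    MortalityTable,
    ParameterBundle,
    validate_bundle,
)

__all__ = [
    "annual_prob_to_monthly",
    "background_mortality",
    "apply_relative_risk",
    "combine_death",
    "build_transition_matrix",
    "run_cohort",
    "microsim_oracle",
    "CohortTrace",
    "ArmTotals",
]

N_STATES = 5
DEAD = HealthState.DEAD.value
MONTHS_PER_YEAR = 12


def annual_prob_to_monthly(p_annual: float) -> float:
    """Convert an annual probability to a monthly one at constant hazard."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability {p_annual} outside [0, 1]")
    return 1.0 - (1.0 - p_annual) ** (1.0 / MONTHS_PER_YEAR)


def background_mortality(age: float, table: MortalityTable) -> float:
    """Annual all-cause death probability at *age* from the life table."""
    return table.annual_prob(age)


def apply_relative_risk(p_hosp: float, rr: float, p_death_row: float) -> float:
    """Scale a hospitalization probability by the treatment RR.

    Clipped so the row stays feasible: the scaled probability never exceeds
    1 minus the death probability sharing the row.
    """
    return min(rr * p_hosp, 1.0 - p_death_row)


def combine_death(p_hf_death: float, p_bg_death: float) -> float:
    """Independent competing risks: either cause kills within the cycle."""
    return 1.0 - (1.0 - p_hf_death) * (1.0 - p_bg_death)


def build_transition_matrix(arm: Arm, age: float, bundle: ParameterBundle) -> np.ndarray:
    """5x5 monthly transition matrix for one arm at one age.

    Row layout (NRH, RH1, RH2, RH3, DEAD): death = HF death combined with
    monthly background mortality; one-step-up rehospitalization (RR-scaled
    in the BNP arm); stay = residual.  DEAD is absorbing.
    """
    violations = validate_bundle(bundle)
    if violations:
        raise ValueError("invalid bundle: " + "; ".join(str(v) for v in violations))
    t = bundle.transitions
    rr = bundle.effects.rr_hosp if arm is Arm.BNP else 1.0
    p_bg = annual_prob_to_monthly(background_mortality(age, bundle.mortality))
    literal = bundle.config.transition_label_mode == "literal-stay"

    mat = np.zeros((N_STATES, N_STATES))
    for s in ALIVE_STATES:
        i = s.value
        p_death = combine_death(t.death(s), p_bg)
        if s is HealthState.RH3:
            p_move = 0.0
        elif literal:
            # printed value read as the stay probability; the move
            # probability is the residual after death, then RR-scaled
            p_move = max(1.0 - t.hosp(s) - p_death, 0.0) * rr
        else:
            p_move = apply_relative_risk(t.hosp(s), rr, p_death)
        p_stay = 1.0 - p_move - p_death
        if p_stay < -1e-12:
            raise ValueError(
                f"infeasible row for state {s.name} at age {age}: "
                f"move {p_move} + death {p_death} > 1"
            )
        p_stay = max(p_stay, 0.0)
        mat[i, i] = p_stay
        if p_move:
            mat[i, i + 1] = p_move
        mat[i, DEAD] = p_death
    mat[DEAD, DEAD] = 1.0
    return mat


@dataclass
class CohortTrace:
    """Per-cycle cohort trajectory for one arm (per-patient scale)."""

    arm: Arm
    occupancy: np.ndarray        # (n_cycles+1, 5) state fractions, cycle 0 first
    ages: np.ndarray             # (n_cycles+1,) cohort age at each cycle start
    cost: np.ndarray             # (n_cycles,) undiscounted cost increment per cycle
    cost_disc: np.ndarray        # (n_cycles,) discounted cost increment
    qaly: np.ndarray             # (n_cycles,) undiscounted QALY increment
    qaly_disc: np.ndarray        # (n_cycles,) discounted QALY increment

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    def totals(self) -> "ArmTotals":
        alive = 1.0 - self.occupancy[:-1, DEAD]
        return ArmTotals(
            arm=self.arm,
            cost=float(self.cost_disc.sum()),
            qaly=float(self.qaly_disc.sum()),
            life_years=float(alive.sum() / MONTHS_PER_YEAR),
            cycles=self.n_cycles,
        )

    def to_frame(self):
        """Tidy per-cycle export: (cycle, age, state, occupancy, disc_cost, disc_qaly)."""
        import pandas as pd

        rows = []
        for cyc in range(self.n_cycles):
            for s in HealthState:
                rows.append({
                    "cycle": cyc,
                    "age": self.ages[cyc],
                    "state": s.name,
                    "occupancy": self.occupancy[cyc, s.value],
                    "disc_cost": self.cost_disc[cyc] if s is HealthState.NRH else np.nan,
                    "disc_qaly": self.qaly_disc[cyc] if s is HealthState.NRH else np.nan,
                })
        return pd.DataFrame(rows)


@dataclass
class ArmTotals:
    arm: Arm
    cost: float          # total discounted cost, USD per patient
    qaly: float          # total discounted QALYs per patient
    life_years: float    # undiscounted life-years per patient
    cycles: int
    cost_se: float = 0.0  # nonzero only for microsimulation estimates
    qaly_se: float = 0.0


def _horizon_cycles(bundle: ParameterBundle) -> int:
    cfg = bundle.config
    lifetime = int(round((cfg.max_age - cfg.start_age) * MONTHS_PER_YEAR))
    if cfg.horizon_years is not None:
        return min(int(round(cfg.horizon_years * MONTHS_PER_YEAR)), lifetime)
    return lifetime


def _state_vectors(arm: Arm, bundle: ParameterBundle) -> tuple[np.ndarray, np.ndarray]:
    costs = bundle.costs.for_arm(arm)
    utils = bundle.utilities.values
    cost_vec = np.array([costs["NRH"], costs["RH1"], costs["RH2"], costs["RH3"], 0.0])
    util_vec = np.array([utils["NRH"], utils["RH1"], utils["RH2"], utils["RH3"], 0.0])
    return cost_vec, util_vec


def run_cohort(arm: Arm, bundle: ParameterBundle) -> CohortTrace:
    """Propagate the cohort occupancy vector to the horizon.

    Cycle 0 places the whole cohort in NRH at the configured start age; the
    transition matrix is rebuilt whenever the cohort crosses into a new
    mortality age band.  Discount factors use (1 + r)^(-t/12) at cycle t.
    Terminates at max_age, at a fixed horizon if configured, or when the
    alive fraction falls below 1e-8.
    """
    violations = validate_bundle(bundle)
    if violations:
        raise ValueError("invalid bundle: " + "; ".join(str(v) for v in violations))
    cfg = bundle.config
    max_cycles = _horizon_cycles(bundle)
    cost_vec, util_vec = _state_vectors(arm, bundle)
    event_mode = cfg.cost_semantics == "event"
    half_cycle = cfg.half_cycle_correction

    occ = np.zeros((max_cycles + 1, N_STATES))
    occ[0, HealthState.NRH.value] = 1.0
    ages = cfg.start_age + np.arange(max_cycles + 1) / MONTHS_PER_YEAR
    cost = np.zeros(max_cycles)
    cost_d = np.zeros(max_cycles)
    qaly = np.zeros(max_cycles)
    qaly_d = np.zeros(max_cycles)

    mat = None
    band_prob = None
    n_done = 0
    for t in range(max_cycles):
        p_band = bundle.mortality.annual_prob(ages[t])
        if mat is None or p_band != band_prob:
            mat = build_transition_matrix(arm, ages[t], bundle)
            band_prob = p_band
        occ[t + 1] = occ[t] @ mat
        # reward basis: start-of-cycle occupancy, or the mid-cycle average
        basis = 0.5 * (occ[t] + occ[t + 1]) if half_cycle else occ[t]
        if event_mode:
            # admission charged once on entry to an RH state; NRH accrues per cycle
            inflow = occ[t, :3] * mat[np.arange(3), np.arange(1, 4)]
            c = basis[HealthState.NRH.value] * cost_vec[0] + float(inflow @ cost_vec[1:4])
        else:
            c = float(basis @ cost_vec)
        q = float(basis @ util_vec) / MONTHS_PER_YEAR
        df_c = (1.0 + bundle.discount.rate_cost) ** (-t / MONTHS_PER_YEAR)
        df_e = (1.0 + bundle.discount.rate_effect) ** (-t / MONTHS_PER_YEAR)
        cost[t], cost_d[t] = c, c * df_c
        qaly[t], qaly_d[t] = q, q * df_e
        n_done = t + 1
        if 1.0 - occ[t + 1, DEAD] < 1e-8:
            break

    return CohortTrace(
        arm=arm,
        occupancy=occ[: n_done + 1],
        ages=ages[: n_done + 1],
        cost=cost[:n_done],
        cost_disc=cost_d[:n_done],
        qaly=qaly[:n_done],
        qaly_disc=qaly_d[:n_done],
    )


def microsim_oracle(
    arm: Arm, bundle: ParameterBundle, n_individuals: int, seed: int
) -> ArmTotals:
    """Individual-level Monte Carlo with the same matrices and discounting.

    Serves as an independent check on the cohort trace: by the law of large
    numbers its mean discounted cost and QALYs converge to the cohort-model
    totals.  Returns means with standard errors.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    cfg = bundle.config
    max_cycles = _horizon_cycles(bundle)
    cost_vec, util_vec = _state_vectors(arm, bundle)
    event_mode = cfg.cost_semantics == "event"
    half_cycle = cfg.half_cycle_correction

    state = np.full(n_individuals, HealthState.NRH.value, dtype=np.int64)
    tot_cost = np.zeros(n_individuals)
    tot_qaly = np.zeros(n_individuals)
    tot_months = np.zeros(n_individuals)

    mat = None
    band_prob = None
    for t in range(max_cycles):
        age = cfg.start_age + t / MONTHS_PER_YEAR
        p_band = bundle.mortality.annual_prob(age)
        if mat is None or p_band != band_prob:
            mat = build_transition_matrix(arm, age, bundle)
            band_prob = p_band
            cum = np.cumsum(mat, axis=1)
        alive = state != DEAD
        if not alive.any():
            break
        u = rng.random(n_individuals)
        nxt = (u[:, None] > cum[state]).sum(axis=1)
        nxt[~alive] = DEAD
        df_c = (1.0 + bundle.discount.rate_cost) ** (-t / MONTHS_PER_YEAR)
        df_e = (1.0 + bundle.discount.rate_effect) ** (-t / MONTHS_PER_YEAR)
        if half_cycle:
            c_now = 0.5 * (cost_vec[state] + cost_vec[nxt])
            q_now = 0.5 * (util_vec[state] + util_vec[nxt])
        else:
            c_now = cost_vec[state]
            q_now = util_vec[state]
        if event_mode:
            admitted = (nxt == state + 1) & (state < 3)
            c_now = np.where(state == HealthState.NRH.value, cost_vec[0], 0.0)
            c_now = c_now + np.where(admitted, cost_vec[np.minimum(nxt, 3)], 0.0)
        tot_cost += np.where(alive, c_now * df_c, 0.0)
        tot_qaly += np.where(alive, q_now / MONTHS_PER_YEAR * df_e, 0.0)
        tot_months += alive
        state = nxt

    return ArmTotals(
        arm=arm,
        cost=float(tot_cost.mean()),
        qaly=float(tot_qaly.mean()),
        life_years=float(tot_months.mean() / MONTHS_PER_YEAR),
        cycles=max_cycles,
        cost_se=float(tot_cost.std(ddof=1) / np.sqrt(n_individuals)),
        qaly_se=float(tot_qaly.std(ddof=1) / np.sqrt(n_individuals)),
    )
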