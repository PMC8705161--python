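"""Sensitivity analysis: distribution fitting, PSA, CEAC, tornado, bootstrap.

Parameter uncertainty is propagated by Monte Carlo: each input is assigned a
distribution by its published family (Beta for probabilities and utilities,
Gamma for costs, log-normal for the hospitalization RR), fitted by the
method of moments to the printed mean and SD, sampled independently, and the
two-arm model re-run per draw.  Several printed SDs sit at or beyond the
Beta feasibility bound sd^2 < m(1-m); those fits are repaired by shrinking
the SD to 95% of the bound and flagged rather than dropped, since silently
discarding rows would change the PSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cea import CEAResult, nmb, run_base_case
from .params import ParameterBundle, PSASpec, validate_bundle

__all__ = [
    "DistributionFit",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_from_moments",
    "fit_spec",
    "PSADraws",
    "run_psa",
    "CEACCurve",
    "ceac",
    "TornadoEntry",
    "tornado",
    "bootstrap_ci",
]

# repair at 95% of the Beta SD bound: fits at/near the bound degenerate into
# near-Bernoulli two-point shapes with alpha, beta << 1
BETA_REPAIR_FRACTION = 0.95


@dataclass
class DistributionFit:
    family: str                 # "beta" | "gamma" | "lognormal"
    params: dict[str, float]    # natural parameters
    mean: float                 # moments actually fitted (post-repair)
    sd: float
    requested_mean: float
    requested_sd: float
    repaired: bool = False

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size=size)
        raise ValueError(f"unknown family {self.family!r}")


def beta_from_moments(mean: float, sd: float) -> DistributionFit:
    """Beta fit by method of moments; SD repaired when it (nearly) breaks
    the feasibility bound sd < sqrt(mean*(1-mean))."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"Beta mean must be in (0, 1), got {mean}")
    if sd <= 0.0:
        raise ValueError(f"Beta sd must be > 0, got {sd}")
    bound = math.sqrt(mean * (1.0 - mean))
    repaired = False
    fit_sd = sd
    if sd >= BETA_REPAIR_FRACTION * bound:
        fit_sd = BETA_REPAIR_FRACTION * bound
        repaired = True
    k = mean * (1.0 - mean) / fit_sd**2 - 1.0
    assert k > 0.0
    alpha = mean * k
    beta = (1.0 - mean) * k
    return DistributionFit(
        family="beta",
        params={"alpha": alpha, "beta": beta},
        mean=alpha / (alpha + beta),
        sd=math.sqrt(alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1.0))),
        requested_mean=mean,
        requested_sd=sd,
        repaired=repaired,
    )


def gamma_from_moments(mean: float, sd: float) -> DistributionFit:
    """Gamma fit by method of moments: shape = (m/s)^2, scale = s^2/m."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError(f"Gamma moments must be positive, got mean={mean}, sd={sd}")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return DistributionFit(
        family="gamma",
        params={"shape": shape, "scale": scale},
        mean=shape * scale,
        sd=math.sqrt(shape) * scale,
        requested_mean=mean,
        requested_sd=sd,
    )


def lognormal_from_moments(mean: float, log_sd: float) -> DistributionFit:
    """Log-normal with a given *arithmetic* mean and log-scale SD.

    mu = ln(mean) - log_sd^2/2 so that E[X] equals the requested mean.
    """
    if mean <= 0.0 or log_sd <= 0.0:
        raise ValueError(f"need positive mean and log_sd, got {mean}, {log_sd}")
    mu = math.log(mean) - log_sd**2 / 2.0
    arith_sd = mean * math.sqrt(math.exp(log_sd**2) - 1.0)
    return DistributionFit(
        family="lognormal",
        params={"mu": mu, "sigma": log_sd},
        mean=mean,
        sd=arith_sd,
        requested_mean=mean,
        requested_sd=log_sd,
    )


def fit_spec(spec: PSASpec) -> DistributionFit:
    if spec.family == "beta":
        return beta_from_moments(spec.mean, spec.sd)
    if spec.family == "gamma":
        return gamma_from_moments(spec.mean, spec.sd)
    if spec.family == "lognormal":
        return lognormal_from_moments(spec.mean, spec.sd)
    raise ValueError(f"unknown distribution family {spec.family!r}")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_TRANSITION_ROWS = (  # (hosp field or None, death field) per alive state
    ("p_hosp_nrh", "p_death_nrh"),
    ("p_hosp_rh1", "p_death_rh1"),
    ("p_hosp_rh2", "p_death_rh2"),
    (None, "p_death_rh3"),
)


@dataclass
class PSADraws:
    seed: int
    n_draws: int
    delta_cost: np.ndarray          # (n_draws,)
    delta_qaly: np.ndarray          # (n_draws,)
    samples: dict[str, np.ndarray]  # per-parameter realizations
    repaired_fits: list[str]        # parameters whose Beta fit was repaired
    renormalized_draws: int         # draws whose sampled row needed rescaling


def _realize_bundle(bundle: ParameterBundle, values: dict[str, float]) -> tuple[ParameterBundle, bool]:
    """Build a bundle realization from sampled values; rescale any transition
    row whose hosp+death sum exceeds 1 (flagged by the caller)."""
    b = bundle.copy()
    renorm = False
    for hosp_f, death_f in _TRANSITION_ROWS:
        death = values[death_f]
        hosp = values[hosp_f] if hosp_f else 0.0
        total = hosp + death
        if total > 1.0:
            hosp, death = hosp / total, death / total
            renorm = True
        if hosp_f:
            setattr(b.transitions, hosp_f, hosp)
        setattr(b.transitions, death_f, death)
    for state in ("NRH", "RH1", "RH2", "RH3"):
        b.costs.bnp[state] = values[f"cost_{state}_BNP"]
        b.costs.standard[state] = values[f"cost_{state}_STANDARD"]
        b.utilities.values[state] = min(values[f"utility_{state}"], 1.0)
    b.effects.rr_hosp = values["rr_hosp"]
    return b, renorm


def run_psa(bundle: ParameterBundle, n_draws: int, seed: int) -> PSADraws:
    """Monte Carlo parameter uncertainty propagation.

    Every stochastic input is sampled from its fitted distribution once per
    draw (the RR once per draw, applied to the BNP arm only via the engine),
    the two-arm model is run, and the incremental (dC, dE) pair stored.
    Fully determined by (seed, bundle, n_draws).
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    fits = {spec.name: fit_spec(spec) for spec in bundle.psa_specs()}
    samples = {name: fit.sample(rng, n_draws) for name, fit in fits.items()}
    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    n_renorm = 0
    for i in range(n_draws):
        values = {name: float(arr[i]) for name, arr in samples.items()}
        realized, renorm = _realize_bundle(bundle, values)
        n_renorm += renorm
        bad = validate_bundle(realized)
        if bad:  # pragma: no cover - renormalization guarantees feasibility
            raise RuntimeError(f"draw {i} infeasible after repair: {bad}")
        res = run_base_case(realized)
        d_cost[i] = res.delta_cost
        d_qaly[i] = res.delta_qaly
    return PSADraws(
        seed=seed,
        n_draws=n_draws,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        samples=samples,
        repaired_fits=[name for name, f in fits.items() if f.repaired],
        renormalized_draws=n_renorm,
    )


@dataclass
class CEACCurve:
    wtp: np.ndarray           # strictly increasing grid, USD/QALY
    probability: np.ndarray   # P(cost-effective) in [0, 1]

    def at(self, wtp_value: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return float(self.probability[idx])


def ceac(draws: PSADraws, wtp_grid) -> CEACCurve:
    """Fraction of draws with positive net monetary benefit at each WTP."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("WTP grid must be strictly increasing")
    nmb_matrix = grid[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    prob = (nmb_matrix > 0).mean(axis=1)
    return CEACCurve(wtp=grid, probability=prob)


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter: str
    low_value: float       # parameter at -20% (post-clip)
    high_value: float      # parameter at +20% (post-clip)
    outcome_low: float
    outcome_high: float
    clipped: bool = False

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _outcome(result: CEAResult, mode: str) -> float:
    if mode == "nmb":
        return result.nmb
    if mode == "icer":
        # sign-unstable around dominance; reported as the raw ratio
        return result.delta_cost / result.delta_qaly if result.delta_qaly != 0 else math.inf
    raise ValueError(f"unknown tornado outcome {mode!r}")


def _set_parameter(bundle: ParameterBundle, name: str, value: float) -> bool:
    """Assign one named model input; returns True if clipping was applied."""
    clipped = False
    if name.startswith("p_"):
        hi = 1.0
        # keep the row feasible against its sibling death/hosp probability
        for hosp_f, death_f in _TRANSITION_ROWS:
            if name == hosp_f:
                hi = 1.0 - getattr(bundle.transitions, death_f)
            elif name == death_f and hosp_f:
                hi = 1.0 - getattr(bundle.transitions, hosp_f)
        v = min(max(value, 0.0), hi)
        clipped = v != value
        setattr(bundle.transitions, name, v)
    elif name.startswith("cost_"):
        _, state, arm = name.split("_")
        target = bundle.costs.bnp if arm == "BNP" else bundle.costs.standard
        target[state] = max(value, 0.0)
        clipped = value < 0.0
    elif name.startswith("utility_"):
        state = name.split("_")[1]
        v = min(max(value, 0.0), 1.0)
        clipped = v != value
        bundle.utilities.values[state] = v
    elif name == "rr_hosp":
        bundle.effects.rr_hosp = value
    else:
        raise ValueError(f"unknown parameter {name!r}")
    return clipped


def tornado(
    bundle: ParameterBundle,
    perturbation: float = 0.20,
    outcome: str = "nmb",
) -> list[TornadoEntry]:
    """One entry per model input: outcome at parameter x(1±perturbation).

    Probabilities and utilities are clipped back into their valid ranges
    (recorded on the entry); entries are sorted by bar width, widest first.
    The default outcome is NMB at the configured WTP because the ICER
    changes sign across the dominance boundary.
    """
    if not 0.0 < perturbation < 1.0:
        raise ValueError("perturbation must be in (0, 1)")
    base = run_base_case(bundle)
    base_out = _outcome(base, outcome)
    entries = []
    for spec in bundle.psa_specs():
        if spec.name == "rr_hosp" and spec.family == "lognormal":
            base_value = bundle.effects.rr_hosp
        else:
            base_value = spec.mean
        results = []
        clipped_any = False
        realized = []
        for factor in (1.0 - perturbation, 1.0 + perturbation):
            b = bundle.copy()
            clipped = _set_parameter(b, spec.name, base_value * factor)
            clipped_any |= clipped
            # read back the post-clip value actually used
            realized.append(base_value * factor if not clipped else _get_parameter(b, spec.name))
            results.append(_outcome(run_base_case(b), outcome))
        entries.append(
            TornadoEntry(
                parameter=spec.name,
                low_value=realized[0],
                high_value=realized[1],
                outcome_low=results[0],
                outcome_high=results[1],
                clipped=clipped_any,
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries, base_out


def _get_parameter(bundle: ParameterBundle, name: str) -> float:
    if name.startswith("p_"):
        return getattr(bundle.transitions, name)
    if name.startswith("cost_"):
        _, state, arm = name.split("_")
        return (bundle.costs.bnp if arm == "BNP" else bundle.costs.standard)[state]
    if name.startswith("utility_"):
        return bundle.utilities.values[name.split("_")[1]]
    if name == "rr_hosp":
        return bundle.effects.rr_hosp
    raise ValueError(name)


# ---------------------------------------------------------------------------
# Non-parametric bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(values, n_reps: int = 1000, seed: int = 0, level: float = 0.95):
    """Percentile bootstrap CI for the mean of per-patient values.

    Resamples with replacement at the original size, n_reps times; returns
    (low, high, point) where point is the plain sample mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to bootstrap")
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_reps, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high), float(arr.mean())
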