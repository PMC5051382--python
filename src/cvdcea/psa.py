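"""Probabilistic sensitivity analysis over the two-arm lifetime model.

Per iteration one joint parameter draw is shared by both arms (common
random numbers: only the intervention's risk path and year-0 inputs differ
between arms, which isolates the intervention signal).  State costs are
drawn from gamma distributions moment-matched to their mean and SE; state
utility multipliers and the standardised mortality ratio from univariate
normals (utilities clamped to [0, 1]).  The unstable-angina multiplier is
tied to 90% of the stable-angina draw, post-event draws are raised to at
least their acute event's draw, and repeat events reuse the first event's
utility and cost parameters.  Incidence shares, secondary transition
probabilities and case fatality are treated as fixed.

Risk paths are not sampled (the risk score's variance structure is not
published), so for a given stratum and scenario the survival-conditional
CVD dynamics are fixed across iterations; only the mortality layer (via
the SMR draw) and the cost/utility vectors vary.  ``StratumModel``
precomputes the fixed part once, which keeps a 1000-iteration PSA fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import ArmResult, accumulate, run_trace
from .risk_trajectory import EffectScenario, build_trajectory, split_events
from .state_space import ExpandedSpace, StateRegistry, default_registry, expand
from .synthetic_data import CohortStratum, ParameterSet
from .transition_model import combine_mortality, cvd_dynamics_matrix

ARM_COLUMNS = ("control_cost", "control_qaly", "intervention_cost", "intervention_qaly")


@dataclass(eq=False)
class RealizedParameters:
    """One joint draw of the sampled parameters, plus the fixed tables."""

    costs: dict[str, float]
    multipliers: dict[str, float]
    smr: float
    params: ParameterSet


def draw_parameters(
    params: ParameterSet,
    rng: np.random.Generator,
    registry: Optional[StateRegistry] = None,
) -> RealizedParameters:
    """Sample one realization of costs, utility multipliers and the SMR.

    Gamma draws use shape ``(mean/se)**2`` and scale ``se**2/mean`` so the
    distribution's mean and SD match the specified values; a zero SE (or a
    zero mean) makes the parameter fixed.  Draw order is the table order,
    so a given generator state yields a reproducible realization.
    """
    reg = registry if registry is not None else default_registry()

    costs: dict[str, float] = {}
    for r in params.state_costs.itertuples():
        mean, se = float(r.mean_gbp), float(r.se_gbp)
        if se == 0.0 or mean == 0.0:
            costs[r.state] = mean
        else:
            shape = (mean / se) ** 2
            costs[r.state] = float(rng.gamma(shape, se**2 / mean))

    mults: dict[str, float] = {}
    for r in params.state_utilities.itertuples():
        if r.state == "unstable_angina":
            continue  # tied to the stable-angina draw below
        mean, se = float(r.multiplier_mean), float(r.multiplier_se)
        draw = mean if se == 0.0 else float(rng.normal(mean, se))
        mults[r.state] = min(1.0, max(0.0, draw))
    if "stable_angina" in mults:
        mults["unstable_angina"] = 0.9 * mults["stable_angina"]

    # a post-event state is never worse than the acute event it follows
    for s in reg.states:
        if s.linked_acute is not None and s.name in mults and s.linked_acute in mults:
            mults[s.name] = max(mults[s.name], mults[s.linked_acute])

    smr = params.smr_mean
    if params.smr_se > 0.0:
        smr = float(rng.normal(params.smr_mean, params.smr_se))
    smr = max(0.0, smr)
    return RealizedParameters(costs=costs, multipliers=mults, smr=smr, params=params)


@dataclass(eq=False)
class StratumModel:
    """Everything about one stratum that is fixed across PSA iterations:
    the risk trajectory, the survival-conditional CVD matrices per cycle,
    the life-table rates, and the utility-norm path."""

    stratum: CohortStratum
    space: ExpandedSpace
    T: int
    m_cvd: list[np.ndarray]
    qx: np.ndarray          # (T,)
    norms: np.ndarray       # (T,) baseline utility at attained age
    cohort_size: float = 1000.0

    def tables(self, smr: float) -> list[np.ndarray]:
        qs = np.minimum(1.0, self.qx * smr)
        return [combine_mortality(m, q, self.space) for m, q in zip(self.m_cvd, qs)]

    def value_vectors(self, realized: RealizedParameters) -> tuple[np.ndarray, np.ndarray]:
        """Cost vector (n,) and utility array (T, n) on the expanded space."""
        cost_vec = np.array(
            [realized.costs.get(s, 0.0) for s in self.space.state_names]
        )
        cost_vec[self.space.dead_mask] = 0.0
        mult_vec = np.array(
            [realized.multipliers.get(s, 0.0) for s in self.space.state_names]
        )
        mult_vec[self.space.dead_mask] = 0.0
        util = self.norms[:, None] * mult_vec[None, :]
        return cost_vec, np.clip(util, 0.0, 1.0)

    def run(self, realized: RealizedParameters, year0_override: bool = True) -> ArmResult:
        initial = np.zeros(self.space.n)
        initial[self.space.event_free_idx] = self.cohort_size
        trace = run_trace(initial, self.tables(realized.smr), space=self.space)
        cost_vec, util = self.value_vectors(realized)
        return accumulate(
            trace,
            cost_vec,
            util,
            stratum=self.stratum,
            discount_rate=realized.params.discount_rate,
            year0_override=year0_override,
        )


def build_stratum_models(
    strata: Sequence[CohortStratum],
    params: ParameterSet,
    scenario: EffectScenario,
    registry: Optional[StateRegistry] = None,
    cohort_size: float = 1000.0,
    repeat_from_acute: bool = False,
) -> list[StratumModel]:
    """Precompute the iteration-invariant model for every stratum.

    Intervention strata are matched to the control stratum of the same sex
    and entry age to apply the duration-of-effect reversion.
    """
    reg = registry if registry is not None else default_registry()
    space = expand(reg)
    controls = {
        (s.sex, s.age0): s for s in strata if s.arm == "control"
    }
    models: list[StratumModel] = []
    for s in strata:
        ctrl = None
        if s.arm == "intervention":
            ctrl = controls.get((s.sex, s.age0))
            if ctrl is None:
                raise ValueError(
                    f"no control stratum matching intervention stratum "
                    f"({s.sex}, age {s.age0})"
                )
        traj = build_trajectory(s, params, scenario, ctrl_stratum=ctrl)
        T = 100 - s.age0
        m_cvd = []
        for t in range(T):
            age = s.age0 + t
            probs = split_events(float(traj.p_annual[t]), age, s.sex, params)
            m_cvd.append(
                cvd_dynamics_matrix(
                    space, age, s.sex, probs, params,
                    repeat_from_acute=repeat_from_acute,
                )
            )
        qx = np.array([params.qx(s.sex, s.age0 + t) for t in range(T)])
        norms = np.array([params.norm(s.sex, s.age0 + t) for t in range(T)])
        models.append(
            StratumModel(
                stratum=s, space=space, T=T, m_cvd=m_cvd, qx=qx, norms=norms,
                cohort_size=cohort_size,
            )
        )
    return models


@dataclass(eq=False)
class PSAResult:
    """Per-iteration per-arm discounted per-patient cost/QALY pairs."""

    scenario: str
    seed: int
    n_iter: int
    data: pd.DataFrame  # iteration + ARM_COLUMNS

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.data["intervention_cost"] - self.data["control_cost"]).to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return (self.data["intervention_qaly"] - self.data["control_qaly"]).to_numpy()

    def save(self, outdir: str | Path) -> None:
        """Long CSV (iteration, scenario, arm, cost, qaly) + JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in self.data.itertuples():
            rows.append((r.iteration, self.scenario, "control", r.control_cost, r.control_qaly))
            rows.append(
                (r.iteration, self.scenario, "intervention", r.intervention_cost, r.intervention_qaly)
            )
        pd.DataFrame(
            rows, columns=["iteration", "scenario", "arm", "cost", "qaly"]
        ).to_csv(outdir / f"psa_{self.scenario}.csv", index=False)
        sidecar = {"seed": self.seed, "n_iter": self.n_iter, "scenario": self.scenario}
        (outdir / f"psa_{self.scenario}.json").write_text(json.dumps(sidecar, indent=2))


def _arm_aggregate(
    models: Sequence[StratumModel], realized: RealizedParameters
) -> dict[str, tuple[float, float]]:
    """Weighted per-patient (cost, qaly) per arm for one realization."""
    out = {"control": [0.0, 0.0], "intervention": [0.0, 0.0]}
    for m in models:
        res = m.run(realized)
        acc = out[m.stratum.arm]
        acc[0] += m.stratum.weight * res.discounted_cost
        acc[1] += m.stratum.weight * res.discounted_qalys
    return {arm: (v[0], v[1]) for arm, v in out.items()}


def run_psa(
    strata: Sequence[CohortStratum],
    params: ParameterSet,
    scenario: EffectScenario,
    n_iter: int = 1000,
    seed: int = 0,
    registry: Optional[StateRegistry] = None,
    cohort_size: float = 1000.0,
    models: Optional[Sequence[StratumModel]] = None,
) -> PSAResult:
    """Run the full two-arm PSA for one duration-of-effect scenario.

    Per-iteration generator substreams are spawned deterministically from
    ``seed`` alone (not the scenario), so different scenarios see the same
    draws and scenario contrasts are free of Monte-Carlo noise.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    reg = registry if registry is not None else default_registry()
    if models is None:
        models = build_stratum_models(
            strata, params, scenario, registry=reg, cohort_size=cohort_size
        )
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    rows = np.empty((n_iter, 4))
    for i in range(n_iter):
        rng = np.random.default_rng(streams[i])
        try:
            realized = draw_parameters(params, rng, registry=reg)
            arms = _arm_aggregate(models, realized)
        except Exception as exc:  # noqa: BLE001 - re-raise with iteration context
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        rows[i] = (
            arms["control"][0],
            arms["control"][1],
            arms["intervention"][0],
            arms["intervention"][1],
        )
    data = pd.DataFrame(rows, columns=list(ARM_COLUMNS))
    data.insert(0, "iteration", np.arange(n_iter))
    return PSAResult(scenario=scenario.label, seed=seed, n_iter=n_iter, data=data)


def run_deterministic(
    strata: Sequence[CohortStratum],
    params: ParameterSet,
    scenario: EffectScenario,
    registry: Optional[StateRegistry] = None,
    cohort_size: float = 1000.0,
) -> dict[str, tuple[float, float]]:
    """The model at parameter means (all SEs zero): per-arm per-patient
    discounted (cost, QALYs)."""
    reg = registry if registry is not None else default_registry()
    zero = params.with_zero_ses()
    models = build_stratum_models(
        strata, zero, scenario, registry=reg, cohort_size=cohort_size
    )
    realized = draw_parameters(zero, np.random.default_rng(0), registry=reg)
    return _arm_aggregate(models, realized)
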