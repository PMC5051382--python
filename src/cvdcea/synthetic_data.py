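"""Trial-like cohort strata and a complete stand-in parameter set.

The cohort entering the model mirrors a UK primary-care trial population
with raised 10-year cardiovascular risk: 80% men with mean entry age 67,
women with mean entry age 69, and arm-specific QRISK2 scores at baseline
and at 12-month follow-up (adjusted for baseline).  Year-0 costs and QALYs
are trial-observed; only the between-arm increments (default +£138 and
+0.012 QALYs in the intervention arm) drive incremental results, so the
control-arm levels are configurable constants.

The parameter tables (state costs, utility multipliers, population utility
norms, incidence shares, secondary-event probabilities, case fatality, life
table, risk growth) are *synthetic stand-ins* with the statistical
structure the analysis assumes.  Every generated table carries a
``provenance`` column marked ``synthetic-default`` so transcribed published
values can replace them table by table via :func:`load_parameter_set`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

EVENTS = ("ami", "stable_angina", "unstable_angina", "tia", "stroke")
CHRONIC = ("post_ami", "post_tia", "post_stroke", "stable_angina", "unstable_angina")
STATES = ("event_free",) + EVENTS + ("post_ami", "post_tia", "post_stroke")
SEXES = ("male", "female")
ARMS = ("control", "intervention")

AGE_BANDS = ("40-49", "50-59", "60-69", "70-79", "80-89", "90-99")

# QRISK2 scores (10-year probabilities) observed in the trial, by arm and
# sex: baseline and 12-month follow-up adjusted for baseline.
TRIAL_RISK = {
    ("control", "male"): (0.3159, 0.3200),
    ("intervention", "male"): (0.3183, 0.3160),
    ("control", "female"): (0.2773, 0.2824),
    ("intervention", "female"): (0.2786, 0.2784),
}


class ParameterError(ValueError):
    """A parameter table failed validation; the message names the cell."""


def age_band(age: float) -> str:
    """Decade band label for an attained age; clamped to the covered range."""
    a = int(min(max(age, 40), 99))
    lo = (a // 10) * 10
    return f"{lo}-{lo + 9}"


def _band_index(band: str) -> int:
    return AGE_BANDS.index(band)


@dataclass(frozen=True)
class CohortStratum:
    """One simulated subgroup: arm x sex x entry age, with its population
    weight, risk scores, and trial-observed year-0 cost and QALYs."""

    arm: str
    sex: str
    age0: int
    weight: float
    baseline_r10: float
    followup_r10: float
    year0_cost: float
    year0_qaly: float


@dataclass(eq=False)
class ParameterSet:
    """All model inputs beyond the cohort itself.

    DataFrame fields follow the CSV schemas written by
    :func:`write_parameter_set`; scalar fields hold the non-CVD
    standardised mortality ratio (mean, SE), the annual discount rate and
    the willingness-to-pay grid.
    """

    state_costs: pd.DataFrame            # state, mean_gbp, se_gbp
    state_utilities: pd.DataFrame        # state, multiplier_mean, multiplier_se
    utility_norms: pd.DataFrame          # sex, age_band, utility
    incidence_shares: pd.DataFrame       # sex, age_band, event, share
    secondary_transitions: pd.DataFrame  # sex, age_band, from_state, to_state, prob
    case_fatality: pd.DataFrame          # event, sex, age_band, prob
    life_table: pd.DataFrame             # sex, age, qx
    male_growth: pd.DataFrame            # age, growth_rate
    smr_mean: float = 0.85
    smr_se: float = 0.05
    discount_rate: float = 0.035
    thresholds: np.ndarray = field(
        default_factory=lambda: np.arange(0, 50001, 500, dtype=float)
    )

    # -- fast lookups --------------------------------------------------

    @cached_property
    def _cost_map(self) -> dict[str, tuple[float, float]]:
        return {
            r.state: (float(r.mean_gbp), float(r.se_gbp))
            for r in self.state_costs.itertuples()
        }

    @cached_property
    def _utility_map(self) -> dict[str, tuple[float, float]]:
        return {
            r.state: (float(r.multiplier_mean), float(r.multiplier_se))
            for r in self.state_utilities.itertuples()
        }

    @cached_property
    def _norm_map(self) -> dict[tuple[str, str], float]:
        return {
            (r.sex, r.age_band): float(r.utility)
            for r in self.utility_norms.itertuples()
        }

    @cached_property
    def _incidence_map(self) -> dict[tuple[str, str], dict[str, float]]:
        out: dict[tuple[str, str], dict[str, float]] = {}
        for r in self.incidence_shares.itertuples():
            out.setdefault((r.sex, r.age_band), {})[r.event] = float(r.share)
        return out

    @cached_property
    def _secondary_map(self) -> dict[tuple[str, str, str], dict[str, float]]:
        out: dict[tuple[str, str, str], dict[str, float]] = {}
        for r in self.secondary_transitions.itertuples():
            out.setdefault((r.sex, r.age_band, r.from_state), {})[r.to_state] = float(
                r.prob
            )
        return out

    @cached_property
    def _fatality_map(self) -> dict[tuple[str, str, str], float]:
        return {
            (r.event, r.sex, r.age_band): float(r.prob)
            for r in self.case_fatality.itertuples()
        }

    @cached_property
    def _qx_map(self) -> dict[tuple[str, int], float]:
        return {
            (r.sex, int(r.age)): float(r.qx) for r in self.life_table.itertuples()
        }

    @cached_property
    def _growth_map(self) -> dict[int, float]:
        return {int(r.age): float(r.growth_rate) for r in self.male_growth.itertuples()}

    def cost(self, state: str) -> tuple[float, float]:
        return self._cost_map[state]

    def utility_multiplier(self, state: str) -> tuple[float, float]:
        return self._utility_map[state]

    def norm(self, sex: str, age: float) -> float:
        return self._norm_map[(sex, age_band(age))]

    def incidence(self, sex: str, age: float) -> dict[str, float]:
        key = (sex, age_band(age))
        if key not in self._incidence_map:
            raise ParameterError(f"no incidence-share row for {key}")
        return self._incidence_map[key]

    def secondary(self, sex: str, age: float, from_state: str) -> dict[str, float]:
        key = (sex, age_band(age), from_state)
        if key not in self._secondary_map:
            raise ParameterError(f"no secondary-transition rows for {key}")
        return self._secondary_map[key]

    def fatality(self, event: str, sex: str, age: float) -> float:
        key = (event, sex, age_band(age))
        if key not in self._fatality_map:
            raise ParameterError(f"no case-fatality row for {key}")
        return self._fatality_map[key]

    def qx(self, sex: str, age: float) -> float:
        key = (sex, int(age))
        if key not in self._qx_map:
            raise ParameterError(f"no life-table row for {key}")
        return self._qx_map[key]

    def growth(self, age: float) -> float:
        key = int(age)
        if key not in self._growth_map:
            raise ParameterError(f"no growth-rate row for age {key}")
        return self._growth_map[key]

    def with_zero_ses(self) -> "ParameterSet":
        """A copy in which every sampled parameter has SE 0 (degenerate
        distributions; a PSA over this set is deterministic)."""
        costs = self.state_costs.copy()
        costs["se_gbp"] = 0.0
        utils = self.state_utilities.copy()
        utils["multiplier_se"] = 0.0
        return replace(
            self, state_costs=costs, state_utilities=utils, smr_se=0.0
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_cohort_strata(
    seed: int = 0,
    *,
    male_weight: float = 0.80,
    male_age: int = 67,
    female_age: int = 69,
    control_year0_cost: float = 2000.0,
    control_year0_qaly: float = 0.79,
    cost_increment: float = 138.0,
    qaly_increment: float = 0.012,
    age_distribution: bool = False,
    age_sd: float = 5.0,
    n_age_points: int = 5,
) -> list[CohortStratum]:
    """Strata for both arms x both sexes at the trial's mean entry ages.

    Deterministic for the default 2x2 grid; ``seed`` is consumed only in
    the optional age-distribution mode, which spreads each sex's weight
    over ``n_age_points`` ages drawn from a normal around the mean
    (truncated to 40-74), for sensitivity work.
    """
    rng = np.random.default_rng(seed)
    strata: list[CohortStratum] = []
    for arm in ARMS:
        year0_cost = control_year0_cost + (cost_increment if arm == "intervention" else 0.0)
        year0_qaly = control_year0_qaly + (qaly_increment if arm == "intervention" else 0.0)
        for sex, mean_age, w_sex in (
            ("male", male_age, male_weight),
            ("female", female_age, 1.0 - male_weight),
        ):
            base, follow = TRIAL_RISK[(arm, sex)]
            if not age_distribution:
                ages_weights = [(mean_age, w_sex)]
            else:
                draws = rng.normal(mean_age, age_sd, size=n_age_points)
                ages = np.clip(np.round(draws), 40, 74).astype(int)
                ages_weights = [(int(a), w_sex / n_age_points) for a in ages]
            for a, w in ages_weights:
                strata.append(
                    CohortStratum(
                        arm=arm,
                        sex=sex,
                        age0=a,
                        weight=w,
                        baseline_r10=base,
                        followup_r10=follow,
                        year0_cost=year0_cost,
                        year0_qaly=year0_qaly,
                    )
                )
    return strata


def _provenance(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["provenance"] = "synthetic-default"
    return df


def generate_parameter_set(
    seed: int = 0, *, unstable_fraction: float = 0.5
) -> ParameterSet:
    """A fully populated, internally consistent synthetic parameter set.

    Values are fixed plausible defaults (no field is sampled), chosen to
    respect the orderings the analysis assumes: acute-event costs exceed
    post-event costs, which exceed the event-free cost of zero; post-event
    utility multipliers are at least those of their acute events; the
    unstable-angina multiplier is 90% of the stable-angina one; life-table
    death probabilities increase with age.  ``unstable_fraction`` splits
    the angina incidence share between unstable and stable angina.
    """
    del seed  # reserved: all defaults are deterministic constants

    costs = pd.DataFrame(
        [
            ("event_free", 0.0, 0.0),
            ("ami", 4200.0, 420.0),
            ("stable_angina", 1900.0, 190.0),
            ("unstable_angina", 3200.0, 320.0),
            ("tia", 2600.0, 260.0),
            ("stroke", 9500.0, 950.0),
            ("post_ami", 500.0, 50.0),
            ("post_tia", 300.0, 30.0),
            ("post_stroke", 1800.0, 180.0),
        ],
        columns=["state", "mean_gbp", "se_gbp"],
    )

    stable_mult, stable_se = 0.80, 0.04
    utilities = pd.DataFrame(
        [
            ("event_free", 1.0, 0.0),
            ("ami", 0.76, 0.04),
            ("stable_angina", stable_mult, stable_se),
            ("unstable_angina", 0.9 * stable_mult, 0.9 * stable_se),
            ("tia", 0.85, 0.04),
            ("stroke", 0.63, 0.05),
            ("post_ami", 0.88, 0.03),
            ("post_tia", 0.90, 0.03),
            ("post_stroke", 0.70, 0.05),
        ],
        columns=["state", "multiplier_mean", "multiplier_se"],
    )

    norm_rows = []
    norm_values = {
        "male": (0.85, 0.83, 0.80, 0.76, 0.71, 0.65),
        "female": (0.84, 0.81, 0.78, 0.73, 0.68, 0.62),
    }
    for sex in SEXES:
        for band, u in zip(AGE_BANDS, norm_values[sex]):
            norm_rows.append((sex, band, u))
    norms = pd.DataFrame(norm_rows, columns=["sex", "age_band", "utility"])

    inc_rows = []
    for sex in SEXES:
        for b, band in enumerate(AGE_BANDS):
            if sex == "male":
                ami = 0.40 - 0.02 * b
                stroke = 0.18 + 0.03 * b
                tia = 0.10
            else:
                ami = 0.32 - 0.02 * b
                stroke = 0.20 + 0.03 * b
                tia = 0.12
            angina = 1.0 - ami - stroke - tia
            shares = {
                "ami": ami,
                "stable_angina": angina * (1.0 - unstable_fraction),
                "unstable_angina": angina * unstable_fraction,
                "tia": tia,
                "stroke": stroke,
            }
            total = sum(shares.values())
            for event in EVENTS:
                inc_rows.append((sex, band, event, shares[event] / total))
    incidence = pd.DataFrame(inc_rows, columns=["sex", "age_band", "event", "share"])

    sec_base = {
        "post_ami": 0.040,
        "post_tia": 0.035,
        "post_stroke": 0.045,
        "stable_angina": 0.030,
        "unstable_angina": 0.050,
    }
    linked = {
        "post_ami": "ami",
        "post_tia": "tia",
        "post_stroke": "stroke",
        "stable_angina": "stable_angina",
        "unstable_angina": "unstable_angina",
    }
    sec_rows = []
    for sex in SEXES:
        sex_fac = 1.0 if sex == "male" else 0.9
        for b, band in enumerate(AGE_BANDS):
            age_fac = 1.0 + 0.15 * b
            for frm in CHRONIC:
                targets = [e for e in EVENTS if e != frm]
                # recurrence of the linked event is weighted double
                weights = {e: (2.0 if e == linked[frm] else 1.0) for e in targets}
                wsum = sum(weights.values())
                total = sec_base[frm] * age_fac * sex_fac
                for e in targets:
                    sec_rows.append((sex, band, frm, e, total * weights[e] / wsum))
    secondary = pd.DataFrame(
        sec_rows, columns=["sex", "age_band", "from_state", "to_state", "prob"]
    )

    cf_base = {
        "ami": 0.30,
        "stroke": 0.25,
        "tia": 0.02,
        "unstable_angina": 0.05,
        "stable_angina": 0.01,
    }
    cf_rows = []
    for event in EVENTS:
        for sex in SEXES:
            sex_fac = 1.0 if sex == "male" else 0.95
            for b, band in enumerate(AGE_BANDS):
                prob = min(0.9, cf_base[event] * (1.0 + 0.10 * b) * sex_fac)
                cf_rows.append((event, sex, band, prob))
    fatality = pd.DataFrame(cf_rows, columns=["event", "sex", "age_band", "prob"])

    # Gompertz-like all-cause mortality, female rates 85% of male.
    ages = np.arange(40, 101)
    a_male = 0.02 / math.exp(0.1 * 70)
    lt_rows = []
    for sex, fac in (("male", 1.0), ("female", 0.85)):
        qx = np.minimum(0.99, fac * a_male * np.exp(0.1 * ages))
        for age, q in zip(ages, qx):
            lt_rows.append((sex, int(age), float(q)))
    life_table = pd.DataFrame(lt_rows, columns=["sex", "age", "qx"])

    g_ages = np.arange(40, 85)
    growth = pd.DataFrame(
        {"age": g_ages, "growth_rate": 0.04 + 0.0005 * (g_ages - 40)}
    )

    return ParameterSet(
        state_costs=_provenance(costs),
        state_utilities=_provenance(utilities),
        utility_norms=_provenance(norms),
        incidence_shares=_provenance(incidence),
        secondary_transitions=_provenance(secondary),
        case_fatality=_provenance(fatality),
        life_table=_provenance(life_table),
        male_growth=_provenance(growth),
    )


# ---------------------------------------------------------------------------
# Validation and IO
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "state_costs": ("costs.csv", ["state", "mean_gbp", "se_gbp"]),
    "state_utilities": ("utilities.csv", ["state", "multiplier_mean", "multiplier_se"]),
    "utility_norms": ("norms.csv", ["sex", "age_band", "utility"]),
    "incidence_shares": ("incidence.csv", ["sex", "age_band", "event", "share"]),
    "secondary_transitions": (
        "secondary.csv",
        ["sex", "age_band", "from_state", "to_state", "prob"],
    ),
    "case_fatality": ("case_fatality.csv", ["event", "sex", "age_band", "prob"]),
    "life_table": ("lifetable.csv", ["sex", "age", "qx"]),
    "male_growth": ("growth.csv", ["age", "growth_rate"]),
}


def validate_parameter_set(ps: ParameterSet) -> list[str]:
    """Check the ParameterSet invariants; one message per breach."""
    v: list[str] = []

    for r in ps.state_costs.itertuples():
        if r.mean_gbp < 0 or r.se_gbp < 0:
            v.append(f"costs.csv: state {r.state!r}: negative mean or SE")

    for r in ps.state_utilities.itertuples():
        if not (0.0 < r.multiplier_mean <= 1.0) and r.state != "event_free":
            v.append(
                f"utilities.csv: state {r.state!r}: multiplier "
                f"{r.multiplier_mean} outside (0, 1]"
            )
        if r.multiplier_se < 0:
            v.append(f"utilities.csv: state {r.state!r}: negative SE")
    um = {r.state: r.multiplier_mean for r in ps.state_utilities.itertuples()}
    if "stable_angina" in um and "unstable_angina" in um:
        if abs(um["unstable_angina"] - 0.9 * um["stable_angina"]) > 1e-9:
            v.append(
                "utilities.csv: unstable_angina multiplier is not 90% of "
                "stable_angina"
            )

    for (sex, band), shares in ps._incidence_map.items():
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-9:
            v.append(f"incidence.csv: row group ({sex}, {band}) sums to {total}")
        for event, s in shares.items():
            if not (0.0 <= s <= 1.0):
                v.append(f"incidence.csv: ({sex}, {band}, {event}) share {s} not a probability")

    for r in ps.secondary_transitions.itertuples():
        if not (0.0 <= r.prob <= 1.0):
            v.append(
                f"secondary.csv: ({r.sex}, {r.age_band}, {r.from_state} -> "
                f"{r.to_state}) prob {r.prob} not a probability"
            )
    for r in ps.case_fatality.itertuples():
        if not (0.0 <= r.prob <= 1.0):
            v.append(
                f"case_fatality.csv: ({r.event}, {r.sex}, {r.age_band}) prob "
                f"{r.prob} not a probability"
            )
    for r in ps.life_table.itertuples():
        if not (0.0 <= r.qx <= 1.0):
            v.append(f"lifetable.csv: ({r.sex}, {r.age}) qx {r.qx} not a probability")
    for sex in ps.life_table["sex"].unique():
        sub = ps.life_table[ps.life_table["sex"] == sex].sort_values("age")
        if not sub["qx"].is_monotonic_increasing:
            v.append(f"lifetable.csv: qx not increasing in age for sex {sex!r}")

    if ps.smr_mean <= 0 or ps.smr_se < 0:
        v.append("scalars: smr mean must be > 0 and SE >= 0")
    if ps.discount_rate < 0:
        v.append("scalars: discount_rate must be >= 0")
    return v


def write_parameter_set(ps: ParameterSet, outdir: str | Path) -> None:
    """Write the CSV tables plus a ``config.yaml`` holding the scalars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _cols) in _TABLE_FILES.items():
        getattr(ps, attr).to_csv(outdir / fname, index=False)
    scalars = {
        "smr_mean": float(ps.smr_mean),
        "smr_se": float(ps.smr_se),
        "discount_rate": float(ps.discount_rate),
        "thresholds": [float(t) for t in ps.thresholds],
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump({"scalars": scalars}))


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load a parameter set from a directory of CSVs + ``config.yaml``.

    Schema and invariant breaches raise :class:`ParameterError` naming the
    offending file and cell; generated and loaded sets are interchangeable
    downstream.
    """
    path = Path(path)
    tables: dict[str, pd.DataFrame] = {}
    for attr, (fname, cols) in _TABLE_FILES.items():
        fpath = path / fname
        if not fpath.exists():
            raise ParameterError(f"missing parameter table {fname}")
        df = pd.read_csv(fpath, float_precision="round_trip")
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParameterError(f"{fname}: missing column(s) {missing}")
        tables[attr] = df

    cfg_path = path / "config.yaml"
    scalars = {}
    if cfg_path.exists():
        scalars = (yaml.safe_load(cfg_path.read_text()) or {}).get("scalars", {})

    ps = ParameterSet(
        **tables,
        smr_mean=float(scalars.get("smr_mean", 0.85)),
        smr_se=float(scalars.get("smr_se", 0.05)),
        discount_rate=float(scalars.get("discount_rate", 0.035)),
        thresholds=np.asarray(
            scalars.get("thresholds", np.arange(0, 50001, 500)), dtype=float
        ),
    )
    violations = validate_parameter_set(ps)
    if violations:
        raise ParameterError("; ".join(violations))
    return ps


def write_strata(strata: Iterable[CohortStratum], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.arm, s.sex, s.age0, s.weight, s.baseline_r10, s.followup_r10,
             s.year0_cost, s.year0_qaly)
            for s in strata
        ],
        columns=["arm", "sex", "age0", "weight", "baseline_r10", "followup_r10",
                 "year0_cost", "year0_qaly"],
    ).to_csv(path, index=False)


def load_strata(path: str | Path) -> list[CohortStratum]:
    df = pd.read_csv(path, float_precision="round_trip")
    strata = [
        CohortStratum(
            arm=r.arm, sex=r.sex, age0=int(r.age0), weight=float(r.weight),
            baseline_r10=float(r.baseline_r10), followup_r10=float(r.followup_r10),
            year0_cost=float(r.year0_cost), year0_qaly=float(r.year0_qaly),
        )
        for r in df.itertuples()
    ]
    for arm in {s.arm for s in strata}:
        total = sum(s.weight for s in strata if s.arm == arm)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"strata.csv: weights for arm {arm!r} sum to {total}")
    return strata
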