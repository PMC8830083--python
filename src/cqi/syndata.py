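"""Deterministic synthetic-cohort generator with a ground-truth ledger.

The generator emits fixture tables in the repository CSV dialect for the
two shipped indicators, together with a ledger recording each patient's
*intended* population membership.  Every planted record is consistent
with its flag by construction — a patient flagged for the numerator
really does get a last-in-period blood pressure below 140/90 — so the
ledger is an engine-independent ground truth: flags are derived while
writing rows, never by evaluating the indicator.

Boundary patients are always planted first (ages 17/18/85/86, a diagnosis
exactly six months into the period, blood pressures at the last in-period
second and at the period end) so every documented boundary decision is
exercised on every run.  A single seeded pseudo-random stream drives the
whole cohort; the same (spec, seed) yields byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from random import Random
from typing import Optional

from dateutil.relativedelta import relativedelta

from . import APACHE_FIXTURE, BP_FIXTURE, load_fixture_indicator
from .cdr import (Coded, EntryRecord, Quantity, schema_from_indicator,
                  write_fixture)
from .model import Indicator

__all__ = ["CohortSpec", "GroundTruthLedger", "generate_cohort",
           "generate_icu_cohort", "SpecError", "LEDGER_FILENAME"]

LEDGER_FILENAME = "ledger.json"


class SpecError(ValueError):
    """Invalid cohort specification (e.g. a probability outside [0, 1])."""


@dataclass
class CohortSpec:
    """Study conditions for the hypertension-control cohort.

    Probabilities are per patient; ages are completed years at the start
    of the measurement period; blood pressures are mmHg.
    """

    n_patients: int = 200
    seed: int = 7
    age_min: int = 16                   # uniform age range, includes
    age_max: int = 95                   # patients outside the 18-85 window
    p_hypertension: float = 0.6
    p_controlled_given_htn: float = 0.55
    p_late_diagnosis: float = 0.1       # hypertension onset after start+6 months
    p_esrd: float = 0.04
    p_dialysis: float = 0.02
    p_transplant: float = 0.01
    p_pregnancy: float = 0.06
    visits_min: int = 0
    visits_max: int = 5
    controlled_sys: tuple[float, float] = (124.0, 8.0)    # mean, sd
    controlled_dia: tuple[float, float] = (76.0, 6.0)
    uncontrolled_sys: tuple[float, float] = (152.0, 10.0)
    uncontrolled_dia: tuple[float, float] = (88.0, 8.0)
    diagnosis_earliest: datetime = datetime(2010, 1, 1)
    period_start: datetime = datetime(2016, 1, 1)
    period_end: datetime = datetime(2017, 1, 1)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SpecError("n_patients must be >= 0")
        for name in ("p_hypertension", "p_controlled_given_htn",
                     "p_late_diagnosis", "p_esrd", "p_dialysis",
                     "p_transplant", "p_pregnancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name}={v} is not a probability in [0, 1]")
        if not 0 <= self.visits_min <= self.visits_max:
            raise SpecError("need 0 <= visits_min <= visits_max")
        if self.age_min > self.age_max or self.age_min < 0:
            raise SpecError("invalid age range")
        if self.period_start >= self.period_end:
            raise SpecError("period_start must precede period_end")


@dataclass
class GroundTruthLedger:
    """Intended per-patient flags and the resulting population sets,
    derived by construction while the fixtures are written."""

    patients: dict[str, dict] = field(default_factory=dict)
    populations: dict[str, list[str]] = field(default_factory=dict)
    expected_count: Optional[int] = None   # ICU count scenario only

    def to_json(self) -> dict:
        out = {"patients": self.patients, "populations": self.populations}
        if self.expected_count is not None:
            out["expected_count"] = self.expected_count
        return out

    def population_sets(self) -> dict[str, set[str]]:
        return {k: set(v) for k, v in self.populations.items()}


# -- helpers ---------------------------------------------------------------

def _paths(ind: Indicator, alias: str) -> dict[str, str]:
    b = ind.binding(alias)
    return {e.element_code: e.element_path for e in b.elements}


def _birth_for_age(period_start: datetime, age: int, rng: Random) -> datetime:
    """A birth date giving exactly `age` completed years at period start."""
    anchor = period_start - relativedelta(years=age)
    return anchor - timedelta(days=rng.randint(0, 364))


def _clipped_normal(rng: Random, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    return round(min(hi, max(lo, rng.gauss(mean, sd))), 0)


def _rand_dt(rng: Random, low: datetime, high: datetime) -> datetime:
    """Uniform timestamp in [low, high) at second precision."""
    span = int((high - low).total_seconds())
    return low + timedelta(seconds=rng.randrange(max(span, 1)))


@dataclass
class _Patient:
    pid: str
    age: int
    hypertension: bool = False
    dx_date: Optional[datetime] = None
    controlled: bool = False
    n_visits: int = 0
    renal: bool = False
    renal_date: Optional[datetime] = None
    pregnancy: bool = False


def _plant_edges(spec: CohortSpec) -> list[_Patient]:
    """Boundary patients planted on every run (ids P00001..P00011)."""
    s = spec.period_start
    six = s + relativedelta(months=6)
    mk = _Patient
    return [
        mk("P00001", 17, hypertension=True, dx_date=s - relativedelta(years=2),
           controlled=True, n_visits=2),                       # under age
        mk("P00002", 18, hypertension=True, dx_date=s - relativedelta(years=1),
           controlled=True, n_visits=2),                       # lower age bound
        mk("P00003", 85, hypertension=True, dx_date=s - relativedelta(years=3),
           controlled=False, n_visits=3),                      # upper age bound
        mk("P00004", 86, hypertension=True, dx_date=s - relativedelta(years=4),
           controlled=False, n_visits=1),                      # over age
        mk("P00005", 50, hypertension=True, dx_date=six,
           controlled=True, n_visits=2),                       # dx exactly at start+6m
        mk("P00006", 50, hypertension=True, dx_date=six + timedelta(days=1),
           controlled=True, n_visits=2),                       # dx just too late
        mk("P00007", 60, hypertension=True, dx_date=s - relativedelta(years=1),
           controlled=True, n_visits=-1),                      # BP at last in-period second
        mk("P00008", 60, hypertension=True, dx_date=s - relativedelta(years=1),
           controlled=True, n_visits=-2),                      # extra BP exactly at period end
        mk("P00009", 40, hypertension=True, dx_date=s - relativedelta(years=1),
           controlled=True, n_visits=2, renal=True,
           renal_date=s - relativedelta(years=1)),             # renal exclusion
        mk("P00010", 30, hypertension=True, dx_date=s - relativedelta(years=1),
           controlled=True, n_visits=2, pregnancy=True),       # pregnancy exclusion
        mk("P00011", 45, hypertension=True, dx_date=s - relativedelta(years=1),
           controlled=True, n_visits=0),                       # no BP visit
    ]


def _random_patient(pid: str, spec: CohortSpec, rng: Random) -> _Patient:
    p = _Patient(pid=pid, age=rng.randint(spec.age_min, spec.age_max))
    p.hypertension = rng.random() < spec.p_hypertension
    if p.hypertension:
        if rng.random() < spec.p_late_diagnosis:
            p.dx_date = _rand_dt(
                rng, spec.period_start + relativedelta(months=6)
                + timedelta(days=1), spec.period_end)
        else:
            p.dx_date = _rand_dt(rng, spec.diagnosis_earliest,
                                 spec.period_start + relativedelta(months=6))
        p.controlled = rng.random() < spec.p_controlled_given_htn
    p.n_visits = rng.randint(spec.visits_min, spec.visits_max)
    if rng.random() < spec.p_esrd:
        p.renal = True
    if rng.random() < spec.p_dialysis:
        p.renal = True
    if rng.random() < spec.p_transplant:
        p.renal = True
    if p.renal:
        p.renal_date = _rand_dt(rng, datetime(2012, 1, 1),
                                spec.period_end - timedelta(days=1))
    p.pregnancy = rng.random() < spec.p_pregnancy
    return p


def generate_cohort(spec: CohortSpec, out_dir: str
                    ) -> tuple[dict[str, int], GroundTruthLedger]:
    """Write fixture tables + ``ledger.json`` for the blood-pressure
    indicator; returns (rows per file, ledger)."""
    spec.validate()
    rng = Random(spec.seed)
    ind = load_fixture_indicator(BP_FIXTURE)
    schema = schema_from_indicator(ind)

    diag = _paths(ind, "DIAG")
    pat = _paths(ind, "PAT")
    birth = _paths(ind, "BIRTH")
    adm = _paths(ind, "ADM")
    img = _paths(ind, "IMG")
    bp = _paths(ind, "BP")
    adm_archetype = ind.binding("ADM").archetype_id

    patients = _plant_edges(spec)[:spec.n_patients]
    for i in range(len(patients) + 1, spec.n_patients + 1):
        patients.append(_random_patient(f"P{i:05d}", spec, rng))

    rows: dict[tuple, list[EntryRecord]] = {key: [] for key in schema.tables}

    def add(alias_paths, alias, values, pid, entry_time):
        b = ind.binding(alias)
        rows[(b.archetype_id, b.template_id)].append(EntryRecord(
            patient_id=pid, archetype_id=b.archetype_id,
            template_id=b.template_id, entry_time=entry_time,
            values={alias_paths[k]: v for k, v in values.items()}))

    ledger = GroundTruthLedger()
    s, e = spec.period_start, spec.period_end
    six = s + relativedelta(months=6)
    renal_codes = ["N18.6", "N185"]

    for idx, p in enumerate(patients):
        birth_dt = _birth_for_age(s, p.age, rng)
        reg_time = min(birth_dt + timedelta(days=1), spec.diagnosis_earliest)
        add(pat, "PAT", {"E0101": f"MRN{idx + 1:06d}"}, p.pid, reg_time)
        add(birth, "BIRTH", {"E0201": birth_dt}, p.pid, reg_time)

        if p.hypertension:
            add(diag, "DIAG", {"E0001": Coded("ICD-10", "I10"),
                               "E0002": p.dx_date}, p.pid, p.dx_date)
        if p.renal:
            code = renal_codes[rng.randrange(2)]
            add(diag, "DIAG", {"E0001": Coded("ICD-10", code),
                               "E0002": p.renal_date}, p.pid, p.renal_date)
        preg_date = None
        if p.pregnancy:
            preg_date = _rand_dt(rng, s, e)
            add(diag, "DIAG", {"E0001": Coded("ICD-10", "Z32.100"),
                               "E0002": preg_date}, p.pid, preg_date)

        # context entries exercised by the auxiliary defines
        for _ in range(rng.randint(0, 2)):
            t = _rand_dt(rng, s, e)
            add(adm, "ADM",
                {"E0301": t,
                 "E0302": Coded(adm_archetype, f"at{rng.randint(14, 22):04d}")},
                p.pid, t)
        if rng.random() < 0.3:
            t = _rand_dt(rng, s, e)
            add(img, "IMG", {"E0401": t}, p.pid, t)

        # blood-pressure visits: the LAST in-period visit carries the
        # controlled/uncontrolled values the flag demands
        def bp_values(controlled: bool) -> dict:
            if controlled:
                sys = _clipped_normal(rng, *spec.controlled_sys, 90, 139)
                dia = _clipped_normal(rng, *spec.controlled_dia, 50, 89)
            else:
                sys = _clipped_normal(rng, *spec.uncontrolled_sys, 140, 210)
                dia = _clipped_normal(rng, *spec.uncontrolled_dia, 60, 110)
            return {"E0501": Quantity(sys, "mmHg"),
                    "E0502": Quantity(dia, "mmHg")}

        if p.n_visits == -1:           # edge: last visit at final in-period second
            times = [_rand_dt(rng, s, e - timedelta(days=30)),
                     e - timedelta(seconds=1)]
            n_visits = 2
        elif p.n_visits == -2:         # edge: decoy visit exactly at period end
            times = [_rand_dt(rng, s, e - timedelta(days=30))]
            n_visits = 1
        else:
            n_visits = p.n_visits
            times = sorted(_rand_dt(rng, s, e) for _ in range(n_visits))
        for i, t in enumerate(times):
            last = i == len(times) - 1
            controlled = p.controlled if last else rng.random() < 0.5
            if last and p.n_visits == -1 and times[-1] == t:
                controlled = p.controlled
            add(bp, "BP", bp_values(controlled), p.pid, t)
        if p.n_visits == -2:
            # outside the half-open period; must not override the last
            # in-period (controlled) reading
            add(bp, "BP", bp_values(not p.controlled), p.pid, e)

        has_visit = n_visits > 0
        in_age = 18 <= p.age <= 85
        ip = in_age and p.hypertension and p.dx_date is not None \
            and p.dx_date <= six
        excl = (p.renal and p.renal_date is not None and p.renal_date < e) \
            or (p.pregnancy and preg_date is not None and s <= preg_date < e)
        numer = ip and not excl and has_visit and p.controlled
        ledger.patients[p.pid] = {
            "age": p.age,
            "hypertension": p.hypertension,
            "diagnosis_date": p.dx_date.isoformat() if p.dx_date else None,
            "controlled": p.controlled,
            "bp_visits_in_period": n_visits,
            "flags": {
                "initial_population": ip,
                "denominator": ip,
                "denominator_exclusions": ip and excl,
                "denominator_exceptions": False,
                "numerator": numer,
                "numerator_exclusions": False,
            },
        }

    pops = {k: sorted(pid for pid, rec in ledger.patients.items()
                      if rec["flags"][k])
            for k in ("initial_population", "denominator",
                      "denominator_exclusions", "denominator_exceptions",
                      "numerator", "numerator_exclusions")}
    ledger.populations = pops

    counts = write_fixture(out_dir, schema, rows)
    _write_ledger(out_dir, spec, ledger)
    return counts, ledger


def generate_icu_cohort(n: int, seed: int, p_high_score: float = 0.3,
                        window_hours: int = 24, out_dir: str = "."
                        ) -> tuple[dict[str, int], GroundTruthLedger]:
    """Fixtures for the APACHE-II count indicator: one ICU admission per
    patient plus score observations planted so the number of qualifying
    patients is known by construction.

    Boundary plants: a qualifying score of exactly 15 at exactly
    admission + ``window_hours`` (counted — the window is closed), a
    decoy high score one second past the window, and a decoy low score
    inside it.
    """
    if n < 0:
        raise SpecError("n must be >= 0")
    if not 0.0 <= p_high_score <= 1.0:
        raise SpecError(f"p_high_score={p_high_score} is not in [0, 1]")
    rng = Random(seed)
    ind = load_fixture_indicator(APACHE_FIXTURE)
    schema = schema_from_indicator(ind)
    adm = _paths(ind, "ADM")
    score = _paths(ind, "SCORE")
    adm_b = ind.binding("ADM")
    score_b = ind.binding("SCORE")
    window = timedelta(hours=window_hours)

    rows: dict[tuple, list[EntryRecord]] = {key: [] for key in schema.tables}
    ledger = GroundTruthLedger()
    expected = 0

    for i in range(1, n + 1):
        pid = f"ICU{i:05d}"
        admit = _rand_dt(rng, datetime(2016, 1, 1), datetime(2016, 12, 1))
        rows[(adm_b.archetype_id, adm_b.template_id)].append(EntryRecord(
            patient_id=pid, archetype_id=adm_b.archetype_id,
            template_id=adm_b.template_id, entry_time=admit,
            values={adm["E0001"]: admit,
                    adm["E0002"]: Coded(adm_b.archetype_id, "at0014")}))

        def add_score(value: int, at: datetime) -> None:
            rows[(score_b.archetype_id, score_b.template_id)].append(
                EntryRecord(patient_id=pid,
                            archetype_id=score_b.archetype_id,
                            template_id=score_b.template_id, entry_time=at,
                            values={score["E0101"]: value}))

        if i == 1 and p_high_score > 0:
            flagged, scores = True, [(15, admit + window)]   # closed bound
        elif i == 2 and n >= 2:
            flagged, scores = False, [(20, admit + window + timedelta(seconds=1))]
        elif i == 3 and n >= 3:
            flagged, scores = False, [(14, admit + timedelta(hours=1))]
        else:
            flagged = rng.random() < p_high_score
            scores = []
            if flagged:
                at = admit + timedelta(seconds=rng.randrange(
                    int(window.total_seconds()) + 1))
                scores.append((rng.randint(15, 45), at))
            # distractors: low score inside, high score outside
            if rng.random() < 0.5:
                scores.append((rng.randint(0, 14), admit + timedelta(
                    seconds=rng.randrange(int(window.total_seconds()) + 1))))
            if rng.random() < 0.3:
                scores.append((rng.randint(15, 45), admit + window
                               + timedelta(hours=rng.randint(1, 72))))
        for value, at in scores:
            add_score(value, at)
        expected += flagged
        ledger.patients[pid] = {"qualifies": flagged,
                                "admit": admit.isoformat(),
                                "n_scores": len(scores)}

    ledger.expected_count = expected
    ledger.populations = {"measure_observation": sorted(
        pid for pid, rec in ledger.patients.items() if rec["qualifies"])}
    counts = write_fixture(out_dir, schema, rows)
    _write_ledger(out_dir, {"n": n, "seed": seed,
                            "p_high_score": p_high_score,
                            "window_hours": window_hours}, ledger)
    return counts, ledger


def _write_ledger(out_dir: str, spec, ledger: GroundTruthLedger) -> None:
    if isinstance(spec, CohortSpec):
        spec_dict = {k: (v.isoformat() if isinstance(v, datetime)
                         else list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(spec).items()}
    else:
        spec_dict = spec
    payload = {"spec": spec_dict, **ledger.to_json()}
    with open(os.path.join(out_dir, LEDGER_FILENAME), "w",
              encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
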