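"""Independent brute-force interpreters for the two shipped indicators.

These oracles deliberately share nothing with the cqi package: they read
the fixture CSVs with the standard library, hard-code file and column
names, and implement the measure logic directly (manual calendar
arithmetic, explicit scans).  Engine results are compared against them
exactly.
"""

from __future__ import annotations

import calendar
import csv
import os
from datetime import datetime, timedelta

DIAG_FILE = "openEHR-EHR-EVALUATION.problem_diagnosis.v1.csv"
PERSON_FILE = "openEHR-DEMOGRAPHIC-PERSON.person-patient.v1.csv"
BIRTH_FILE = ("openEHR-DEMOGRAPHIC-CLUSTER.person_birth_data_iso.v1__"
              "patient_demographics.t.v1.csv")
BP_FILE = "openEHR-EHR-OBSERVATION.blood_pressure.v1.csv"
ADM_FILE = "openEHR-EHR-ADMIN_ENTRY.admission.v1.csv"
SCORE_FILE = "openEHR-EHR-OBSERVATION.apache_ii.v0.csv"

DIAG_CODE = "/data[at0001]/items[at0002]/value"
DIAG_DATE = "/data[at0001]/items[at0003]/value"
BIRTH_DATE = "/items[at0001]/value"
BP_SYS = "/data[at0001]/events[at0006]/data[at0003]/items[at0004]/value"
BP_DIA = "/data[at0001]/events[at0006]/data[at0003]/items[at0005]/value"
ADM_TIME = "/data[at0001]/items[at0071]/value"
ADM_TYPE = "/data[at0001]/items[at0013]/value"
SCORE_VAL = "/data[at0001]/events[at0002]/data[at0003]/items[at0004]/value"

RENAL_CODES = {"N185", "N18.6"}


def _rows(data_dir: str, name: str) -> list[dict]:
    path = os.path.join(data_dir, name)
    if not os.path.exists(path):
        return []
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _dt(text: str) -> datetime:
    return datetime.fromisoformat(text)


def _completed_years(birth: datetime, at: datetime) -> int:
    return at.year - birth.year - (
        (at.month, at.day, at.hour, at.minute, at.second)
        < (birth.month, birth.day, birth.hour, birth.minute, birth.second))


def _plus_months(d: datetime, months: int) -> datetime:
    month_index = d.month - 1 + months
    year = d.year + month_index // 12
    month = month_index % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return d.replace(year=year, month=month, day=day)


def _quantity(text: str) -> float:
    return float(text.split("|", 1)[0])


def _coded(text: str) -> tuple[str, str]:
    system, code = text.split("|", 1)
    return system, code


def bp_populations(data_dir: str,
                   period_start: datetime = datetime(2016, 1, 1),
                   period_end: datetime = datetime(2017, 1, 1)) -> dict:
    """Population sets of the blood-pressure-control measure, by direct
    scan of the fixture rows."""
    six_months = _plus_months(period_start, 6)

    persons = {r["patient_id"] for r in _rows(data_dir, PERSON_FILE)}
    births = {r["patient_id"]: _dt(r[BIRTH_DATE])
              for r in _rows(data_dir, BIRTH_FILE)}
    diags: dict[str, list[tuple[str, datetime]]] = {}
    for r in _rows(data_dir, DIAG_FILE):
        system, code = _coded(r[DIAG_CODE])
        if system != "ICD-10" or not r[DIAG_DATE]:
            continue
        diags.setdefault(r["patient_id"], []).append(
            (code, _dt(r[DIAG_DATE])))
    bps: dict[str, list[tuple[datetime, float, float]]] = {}
    for r in _rows(data_dir, BP_FILE):
        bps.setdefault(r["patient_id"], []).append(
            (_dt(r["entry_time"]), _quantity(r[BP_SYS]),
             _quantity(r[BP_DIA])))

    all_patients = persons | set(births) | set(diags) | set(bps)
    ip, excl, numer = set(), set(), set()
    for pid in all_patients:
        if pid not in persons or pid not in births:
            continue
        age = _completed_years(births[pid], period_start)
        has_htn = any(code == "I10" and date <= six_months
                      for code, date in diags.get(pid, []))
        if not (18 <= age <= 85 and has_htn):
            continue
        ip.add(pid)
        renal = any(code in RENAL_CODES and date < period_end
                    for code, date in diags.get(pid, []))
        pregnant = any(code == "Z32.100"
                       and period_start <= date < period_end
                       for code, date in diags.get(pid, []))
        if renal or pregnant:
            excl.add(pid)
        in_period = [(t, s, d) for t, s, d in bps.get(pid, [])
                     if period_start <= t < period_end]
        if in_period:
            # latest entry time; ties -> latest file order (scan keeps >=)
            last = in_period[0]
            for entry in in_period[1:]:
                if entry[0] >= last[0]:
                    last = entry
            if last[1] < 140 and last[2] < 90:
                numer.add(pid)

    effective = ip - excl
    return {
        "initial_population": ip,
        "denominator": set(ip),
        "denominator_exclusions": excl,
        "denominator_exceptions": set(),
        "numerator": numer & effective,
        "numerator_exclusions": set(),
        "effective_denominator": effective,
    }


def apache_count(data_dir: str, window_hours: int = 24) -> int:
    """Number of patients with any APACHE II score >= 15 within
    ``window_hours`` (inclusive) after their first ICU admission."""
    admits: dict[str, datetime] = {}
    for r in _rows(data_dir, ADM_FILE):
        if _coded(r[ADM_TYPE])[1] != "at0014":
            continue
        t = _dt(r[ADM_TIME])
        if r["patient_id"] not in admits or t < admits[r["patient_id"]]:
            admits[r["patient_id"]] = t
    count = 0
    scores: dict[str, list[tuple[datetime, float]]] = {}
    for r in _rows(data_dir, SCORE_FILE):
        scores.setdefault(r["patient_id"], []).append(
            (_dt(r["entry_time"]), float(r[SCORE_VAL])))
    for pid, admit in admits.items():
        hi = admit + timedelta(hours=window_hours)
        if any(v >= 15 and admit <= t <= hi
               for t, v in scores.get(pid, [])):
            count += 1
    return count
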