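// Controlling high blood pressure: percentage of patients 18-85 years of
// age with a diagnosis of essential hypertension whose blood pressure was
// adequately controlled (<140/90 mmHg) during the measurement period.

metadata
    indicator: "Controlling High Blood Pressure"
    version: "1.0.0"
    language: "en"
    translation: "zh-CN|en"
    description: "Percentage of patients 18-85 years of age who had a diagnosis of essential hypertension within the first six months of the measurement period or any time prior, and whose blood pressure at the most recent visit in the period was adequately controlled (systolic < 140 mmHg and diastolic < 90 mmHg). Patients with end stage renal disease, dialysis or renal transplant before or during the period, or a diagnosis of pregnancy during the period, are excluded."
    status: "PUBLISHED"
    author: "Quality Measurement Group"
    time: "2016-05-10T09:30:00"
    email: "quality@example.org"

terminology
    term "ICD-10" uri "http://hl7.org/fhir/sid/icd-10" {
        bind HTN = [I10];
        bind RENAL = [N185 or N18.6];
        bind PREGNANCY = [Z32.100];
    }
    term "openEHR-EHR-ADMIN_ENTRY.admission.v1" {
        bind ADMISSIONTYPE = [at0014-at0022];
    }

archetypes
    archetype DIAG: name "openEHR-EHR-EVALUATION.problem_diagnosis.v1"
        elements {
            E0001 = "/data[at0001]/items[at0002]/value";
            E0002 = "/data[at0001]/items[at0003]/value";
        }
    archetype PAT: name "openEHR-DEMOGRAPHIC-PERSON.person-patient.v1"
        elements {
            E0101 = "/details[at0001]/items[at0003]/value";
        }
    archetype BIRTH: name "openEHR-DEMOGRAPHIC-CLUSTER.person_birth_data_iso.v1"
        in template "patient_demographics.t.v1" with path "/content[openEHR-DEMOGRAPHIC-PERSON.person-patient.v1]/details"
        elements {
            E0201 = "/items[at0001]/value";
        }
    archetype ADM: name "openEHR-EHR-ADMIN_ENTRY.admission.v1"
        elements {
            E0301 = "/data[at0001]/items[at0071]/value";
            E0302 = "/data[at0001]/items[at0013]/value";
        }
    archetype IMG: name "openEHR-EHR-OBSERVATION.imaging_exam.v0"
        elements {
            E0401 = "/data[at0001]/events[at0002]/data[at0003]/items[at0024]/value";
        }
    archetype BP: name "openEHR-EHR-OBSERVATION.blood_pressure.v1"
        elements {
            E0501 = "/data[at0001]/events[at0006]/data[at0003]/items[at0004]/value";
            E0502 = "/data[at0001]/events[at0006]/data[at0003]/items[at0005]/value";
        }
        with predicates {
            E0501 > 0;
            E0502 > 0;
        }

logic
    parameter MeasurementPeriod: Interval<DateTime> default Interval[@2016-01-01T00:00:00, @2017-01-01T00:00:00)

    define "HypertensionOnset":
        [DIAG : HTN] where E0002 <= start of MeasurementPeriod + 6 months

    define "InitialPopulation":
        exists([PAT])
        and exists("HypertensionOnset")
        and AgeInYearsAt(First([BIRTH] sort by entry_time).E0201, start of MeasurementPeriod) >= 18
        and AgeInYearsAt(First([BIRTH] sort by entry_time).E0201, start of MeasurementPeriod) <= 85

    define "Denominator":
        "InitialPopulation"

    define "DenominatorExclusions":
        exists([DIAG : RENAL] where E0002 < end of MeasurementPeriod)
        or exists([DIAG : PREGNANCY] where E0002 during MeasurementPeriod)

    define "MostRecentBP":
        Last([BP] where entry_time during MeasurementPeriod sort by entry_time)

    define "Numerator":
        "MostRecentBP".E0501 < 140 and "MostRecentBP".E0502 < 90

    define "PeriodAdmissions":
        [ADM : ADMISSIONTYPE] where entry_time during MeasurementPeriod

    define "PeriodImagingResults":
        [IMG] where E0401 during MeasurementPeriod
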