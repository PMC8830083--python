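// Count the patients whose APACHE II score is not less than 15 within
// 24 hours after entering the ICU.  "Within 24 h" is read inclusively:
// a score recorded exactly 24 hours after admission still qualifies.

metadata
    indicator: "High APACHE II Score Within 24 Hours of ICU Admission"
    version: "1.0.0"
    language: "en"
    description: "Number of patients whose APACHE II score is not less than 15 within 24 hours after entering the ICU."
    status: "PUBLISHED"
    author: "Quality Measurement Group"
    time: "2016-06-02T14:00:00"
    email: "quality@example.org"

terminology
    term "openEHR-EHR-ADMIN_ENTRY.admission.v1" {
        bind ICUADMIT = [at0014];
    }

archetypes
    archetype ADM: name "openEHR-EHR-ADMIN_ENTRY.admission.v1"
        elements {
            E0001 = "/data[at0001]/items[at0071]/value";
            E0002 = "/data[at0001]/items[at0013]/value";
        }
    archetype SCORE: name "openEHR-EHR-OBSERVATION.apache_ii.v0"
        elements {
            E0101 = "/data[at0001]/events[at0002]/data[at0003]/items[at0004]/value";
        }

logic
    parameter MeasurementPeriod: Interval<DateTime> default Interval[@2016-01-01T00:00:00, @2017-01-01T00:00:00)

    define "IcuAdmitTime":
        First([ADM : ICUADMIT] sort by entry_time).E0001

    define "ScoreWindow":
        Interval["IcuAdmitTime", "IcuAdmitTime" + 24 hours]

    define "MeasureObservation":
        exists([SCORE] where E0101 >= 15 and entry_time during "ScoreWindow")
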