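alias,canonical,uri
ICD10,ICD-10,http://hl7.org/fhir/sid/icd-10
ICD9,ICD-9,http://hl7.org/fhir/sid/icd-9-cm
SNOMEDCT,SNOMED-CT,http://snomed.info/sct
LOINC,LOINC,http://loinc.org
ATC,ATC-WHO,http://www.whocc.no/atc
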