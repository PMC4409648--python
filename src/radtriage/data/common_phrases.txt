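# Common clinical phrases collapsed to single tokens before feature
# extraction (one per line; '#' lines ignored). Longest-match-first
# ordering is enforced at load time, not here.
No significant abnormality is identified
No mammographic change or evidence of malignancy
No acute cardiopulmonary process
No acute pulmonary process
Within normal limits
Normal abdominal ultrasound
No acute intracranial process
Appropriate for age
Routine annual screening mammogram
No acute pathology
Correlation recommended
Biopsy should be performed
Surgical consultation is suggested
Appear significantly changed
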