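# Synthetic facility/person names used by the PHI scrubber's lexical
# look-up. These are invented strings (also planted by the synthetic
# report generator); they are not a certified de-identification list.
MERCY HOSPITAL
BLUE HILLS IMAGING CENTER
ST VINCENT MEDICAL CENTER
RIVERSIDE RADIOLOGY ASSOCIATES
LAKESIDE COMMUNITY HOSPITAL
GREENFIELD DIAGNOSTIC IMAGING
DR SMITH
DR JONES
DR PATEL
DR NGUYEN
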