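# Title phrases marking non-research article types to exclude.
# One term per line; matched case-insensitively on word boundaries.
case report
case reports
case series
a committee opinion
committee opinion
letter to the editor
editorial
commentary
erratum
corrigendum
retraction
retracted
guideline
guidelines
consensus statement
practice bulletin
author reply
reply to
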