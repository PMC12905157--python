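# Default exclusion ruleset for an EGA-Submission-API-style model.
- {category: non_defined, match: "extra attributes"}
- {category: framework_specific, match: "provisional id*"}
- {category: linking, match: "* accession_id"}
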