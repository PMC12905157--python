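# Default exclusion ruleset for an ISA-tab-style serialized model.
- {category: non_defined, match: comments}
- {category: non_defined, match: "comment*"}
- {category: linking, match: "* id"}
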