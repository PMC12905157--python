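# Ruleset matching the excluded-category properties injected by the
# synthetic ensemble generator.
- {category: linking, match: alias}
- {category: non_defined, match: attributes}
- {category: framework_specific, match: "ega accession"}
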