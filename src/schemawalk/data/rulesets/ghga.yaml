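# Default exclusion ruleset for a GHGA-style archive schema: linking
# aliases, archive accessions, ontology-term-ID companion slots,
# submission flags and the free-form attribute catch-all.
- {category: linking, match: alias}
- {category: linking, match: "* alias"}
- {category: non_defined, match: attributes}
- {category: framework_specific, match: "ega accession*"}
- {category: framework_specific, match: "* ids"}
- {category: framework_specific, match: "included in submission"}
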