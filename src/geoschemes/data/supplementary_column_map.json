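{
  "_comment": "Column-mapping configuration for reading a geounit spreadsheet whose headers differ from the canonical schema. Keys are canonical names, values the spreadsheet's actual column headers; adjust to match the vendored file.",
  "code": "Code",
  "label": "Label",
  "level": "Level",
  "parent": "Parent",
  "category": "Category",
  "source_scheme": "Source",
  "country_iso": "ISO"
}
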