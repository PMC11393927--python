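{
  "de": ["sch", "ch", "ie", "ah", "ei", "eu"],
  "en": ["ea", "au", "oa", "aw"],
  "fr": ["eau", "eaux", "au", "en", "ou"]
}
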