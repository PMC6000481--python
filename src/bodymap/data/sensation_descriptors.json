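[
  "burning",
  "cold",
  "cramping",
  "dull",
  "electric",
  "heavy",
  "hot",
  "numb",
  "pressing",
  "pricking",
  "radiating",
  "shooting",
  "stabbing",
  "tearing",
  "tender",
  "throbbing",
  "tingling",
  "tugging"
]
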