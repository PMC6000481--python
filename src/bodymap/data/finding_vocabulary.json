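{
  "pain_paresthesia": [
    "burning", "cold", "cramping", "dull", "electric", "heavy", "hot",
    "numb", "pressing", "pricking", "radiating", "shooting", "stabbing",
    "tender", "throbbing", "tingling", "tugging", "other"
  ],
  "skin_sensitivity": [
    "allodynia", "analgesia", "anesthesia", "dysesthesia", "hypoesthesia",
    "hyperalgesia", "hypoalgesia", "pallanesthesia", "pallhypesthesia",
    "thermanesthesia", "thermhypesthesia", "other"
  ],
  "skin_perfusion": [
    "cyanosis", "hyperthermia", "hypothermia", "pallor", "redness",
    "swelling", "other"
  ],
  "skin_autonomic": [
    "anhidrosis", "atrophy", "hyperhidrosis", "hypertrophy",
    "piloerection", "other"
  ],
  "muscle": [
    "allodynia", "atrophy", "disturbed_proprioception", "fasciculation",
    "hyperalgesia", "hypotonia", "muscular_defense", "myogelosis",
    "rebound_tenderness", "rigor", "spasm", "tenderness", "other"
  ],
  "organ": [
    "tenderness", "hypertrophy", "induration", "other"
  ]
}
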