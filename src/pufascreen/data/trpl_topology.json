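{
  "name": "TRPL membrane topology (synthetic calibrated fixture)",
  "comment": "Boundaries are a calibrated stand-in: exact S1-S6 residue limits for Drosophila TRPL are not published, so these intervals were chosen once to satisfy every printed per-position region assignment (438-522 within S2-S4, 465/471 in S3, 631 in the pore, 742-794 proximal C-terminal, 833 distal). Fully overridable.",
  "pore_exclusion": [595, 670],
  "window_margin": 10,
  "regions": [
    {"region": "N-term", "start": 1, "end": 374},
    {"region": "S1", "start": 375, "end": 398},
    {"region": "S1-S2 linker", "start": 399, "end": 421},
    {"region": "S2", "start": 422, "end": 444},
    {"region": "S2-S3 linker", "start": 445, "end": 457},
    {"region": "S3", "start": 458, "end": 480},
    {"region": "S3-S4 linker", "start": 481, "end": 499},
    {"region": "S4", "start": 500, "end": 525},
    {"region": "S4-S5 linker", "start": 526, "end": 570},
    {"region": "S5", "start": 571, "end": 594},
    {"region": "pore", "start": 595, "end": 650},
    {"region": "S6", "start": 651, "end": 700},
    {"region": "proximal C-term", "start": 701, "end": 800},
    {"region": "distal C-term", "start": 801, "end": 1124}
  ]
}
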