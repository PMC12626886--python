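{
  "arabidopsis": [
    "NUP160",
    "NUP85",
    "NUP43",
    "SEH1",
    "NUP96",
    "SEC13",
    "NUP107",
    "NUP133",
    "HOS1"
  ],
  "human": [
    "NUP160",
    "NUP85",
    "NUP43",
    "SEH1",
    "NUP96",
    "SEC13",
    "NUP107",
    "NUP133",
    "ELYS",
    "NUP37"
  ],
  "homologue_map": {"HOS1": "ELYS"},
  "nup_catalogue": [
    "ALADIN", "NUP50C", "HOS1", "NUP205", "GP210", "NUP35", "NUP43",
    "NUP50B", "NUP54", "NUP58", "NUP62", "NUP82", "NUP85", "NUP88",
    "NUP93A", "NUP93B", "NUP96", "NUP98A", "NUP107", "NUP133", "NUP155",
    "NUP160", "NUP214", "NUA", "NUP188", "NDC1", "GLE1", "RAE1", "SEH1",
    "SEC13A", "SEC13B",
    "NUP50A", "NUP136", "CG1", "NUP98B", "GBPL3", "CPR5"
  ]
}
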