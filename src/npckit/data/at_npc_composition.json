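{
  "name": "AtNPC-default",
  "symmetry_order": 8,
  "homologue_map": {"HOS1": "ELYS"},
  "rings": {
    "CR": [
      {
        "subcomplex": "Y-complex",
        "copies": 1,
        "members": [
          {"species": "NUP160", "copies": 1},
          {"species": "NUP85", "copies": 1},
          {"species": "SEH1", "copies": 1},
          {"species": "NUP43", "copies": 1},
          {"species": "NUP96", "copies": 1},
          {"species": "SEC13A|SEC13B", "copies": 1},
          {"species": "NUP107", "copies": 1},
          {"species": "NUP133", "copies": 1},
          {"species": "HOS1", "copies": 1}
        ]
      },
      {
        "subcomplex": "NUP214-complex",
        "copies": 1,
        "members": [
          {"species": "NUP214", "copies": 1},
          {"species": "NUP88", "copies": 1},
          {"species": "NUP62", "copies": 1}
        ]
      },
      {
        "subcomplex": "NUP205-NUP93",
        "copies": 2,
        "members": [
          {"species": "NUP205", "copies": 1},
          {"species": "NUP93A|NUP93B", "copies": 1}
        ]
      },
      {
        "subcomplex": "connector",
        "copies": 1,
        "members": [
          {"species": "NUP155", "copies": 1}
        ]
      }
    ],
    "IR": [
      {
        "subcomplex": "IR-core",
        "copies": 2,
        "members": [
          {"species": "NUP205", "copies": 1},
          {"species": "NUP93A|NUP93B", "copies": 1}
        ]
      },
      {
        "subcomplex": "channel",
        "copies": 2,
        "members": [
          {"species": "NUP54", "copies": 1},
          {"species": "NUP58", "copies": 1},
          {"species": "NUP62", "copies": 1}
        ]
      },
      {
        "subcomplex": "connector",
        "copies": 2,
        "members": [
          {"species": "NUP155", "copies": 1}
        ]
      },
      {
        "subcomplex": "NUP35-dimer",
        "copies": 1,
        "members": [
          {"species": "NUP35", "copies": 2}
        ]
      },
      {
        "subcomplex": "transmembrane",
        "copies": 1,
        "members": [
          {"species": "NDC1", "copies": 1},
          {"species": "ALADIN", "copies": 1}
        ]
      }
    ],
    "NR": [
      {
        "subcomplex": "Y-complex",
        "copies": 2,
        "members": [
          {"species": "NUP160", "copies": 1},
          {"species": "NUP85", "copies": 1},
          {"species": "SEH1", "copies": 1},
          {"species": "NUP43", "copies": 1},
          {"species": "NUP96", "copies": 1},
          {"species": "SEC13A|SEC13B", "copies": 1},
          {"species": "NUP107", "copies": 1},
          {"species": "NUP133", "copies": 1},
          {"species": "HOS1", "copies": 1}
        ]
      },
      {
        "subcomplex": "NUP205-NUP93",
        "copies": 1,
        "members": [
          {"species": "NUP205", "copies": 1},
          {"species": "NUP93A|NUP93B", "copies": 1}
        ]
      },
      {
        "subcomplex": "connector",
        "copies": 1,
        "members": [
          {"species": "NUP155", "copies": 1}
        ]
      }
    ]
  },
  "optional": [
    {
      "ring": "NR",
      "subcomplex": "outer-Y-head-to-tail-propeller",
      "copies": 1,
      "enabled": false,
      "members": [
        {"species": "NUP133", "copies": 1}
      ],
      "note": "extra density plausibly matching a beta-propeller at the NR outer Y-complex head-to-tail contact; disabled by default"
    }
  ]
}
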