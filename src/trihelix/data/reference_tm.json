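{
  "_comment": "Published characterization of four designed heterotrimers: predicted and CD-measured melting temperatures (degC) of every peptide combination, the derived specificities, and the predicted-vs-experimental comparison for the target assemblies. Cells below the 10 degC reporting floor carry floor=true with tm=10.0; missing combinations (A2B designs have no C strand) are omitted. Note the ABC-FOGER experimental Tm appears as 40.5 in the combination table but 40.7 in the comparison table; both are stored verbatim.",
  "predicted": {
    "rows": {
      "ABC-1": {
        "A": {"tm": 10.0, "floor": true},
        "B": {"tm": 10.0, "floor": true},
        "C": {"tm": 10.0, "floor": true},
        "AB": {"tm": 23.6, "register": "ABB"},
        "AC": {"tm": 14.0, "register": "AAC"},
        "BC": {"tm": 23.7, "register": "BCC"},
        "ABC": {"tm": 39.7, "register": "ABC"}
      },
      "ABC-2": {
        "A": {"tm": 14.3},
        "B": {"tm": 15.1},
        "C": {"tm": 17.7},
        "AB": {"tm": 33.7, "register": "AAB"},
        "AC": {"tm": 28.3, "register": "ACC"},
        "BC": {"tm": 37.6, "register": "CBC"},
        "ABC": {"tm": 63.9, "register": "ABC"}
      },
      "AAB-FOGER": {
        "A": {"tm": 28.4},
        "B": {"tm": 10.0, "floor": true},
        "AB": {"tm": 45.8, "register": "AAB"}
      },
      "ABC-FOGER": {
        "A": {"tm": 10.0, "floor": true},
        "B": {"tm": 10.0, "floor": true},
        "C": {"tm": 14.0},
        "AB": {"tm": 22.8, "register": "ABB"},
        "AC": {"tm": 22.9, "register": "ACC"},
        "BC": {"tm": 24.9, "register": "CBC"},
        "ABC": {"tm": 47.5, "register": "ABC"}
      }
    },
    "specificity": {
      "ABC-1": 16.0,
      "ABC-2": 26.3,
      "AAB-FOGER": 17.4,
      "ABC-FOGER": 22.6
    }
  },
  "experimental": {
    "rows": {
      "ABC-1": {
        "A": {"tm": 11.0},
        "B": {"tm": 10.0, "floor": true},
        "C": {"tm": 10.0, "floor": true},
        "AB": {"tm": 19.5},
        "AC": {"tm": 17.5},
        "BC": {"tm": 20.0},
        "ABC": {"tm": 33.5}
      },
      "ABC-2": {
        "A": {"tm": 10.0, "floor": true},
        "B": {"tm": 17.0},
        "C": {"tm": 10.0, "floor": true},
        "AB": {"tm": 22.5},
        "AC": {"tm": 15.5},
        "BC": {"tm": 21.0},
        "ABC": {"tm": 38.5}
      },
      "AAB-FOGER": {
        "A": {"tm": 18.5},
        "B": {"tm": 14.5},
        "AB": {"tm": 34.5}
      },
      "ABC-FOGER": {
        "A": {"tm": 10.0, "floor": true},
        "B": {"tm": 10.0, "floor": true},
        "C": {"tm": 13.0},
        "AB": {"tm": 20.0},
        "AC": {"tm": 26.0},
        "BC": {"tm": 21.5},
        "ABC": {"tm": 40.5}
      }
    },
    "specificity": {
      "ABC-1": 13.5,
      "ABC-2": 16.0,
      "AAB-FOGER": 16.0,
      "ABC-FOGER": 14.5
    }
  },
  "comparison": {
    "ABC-1": {"predicted": 39.7, "experimental": 33.5, "deviation": 6.2},
    "ABC-2": {"predicted": 63.9, "experimental": 38.5, "deviation": 25.4},
    "AAB-FOGER": {"predicted": 45.8, "experimental": 34.5, "deviation": 11.3},
    "ABC-FOGER": {"predicted": 47.5, "experimental": 40.7, "deviation": 6.8}
  }
}
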