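{
  "description": "Synthetic eczematous-dermatitis toy knowledge base used in examples and tests.",
  "findings": [
    "spongiosis",
    "eosinophilic spongiosis",
    "parakeratosis with neutrophils",
    "regular acanthosis",
    "intraepidermal vesicle",
    "serum crust"
  ],
  "diagnoses": [
    "allergic contact dermatitis",
    "nummular dermatitis",
    "psoriasis",
    "seborrheic dermatitis"
  ],
  "relations": [
    {"finding": "spongiosis", "diagnosis": "allergic contact dermatitis", "polarity": "support"},
    {"finding": "eosinophilic spongiosis", "diagnosis": "allergic contact dermatitis", "polarity": "support"},
    {"finding": "intraepidermal vesicle", "diagnosis": "allergic contact dermatitis", "polarity": "support"},
    {"finding": "spongiosis", "diagnosis": "nummular dermatitis", "polarity": "support"},
    {"finding": "serum crust", "diagnosis": "nummular dermatitis", "polarity": "support"},
    {"finding": "parakeratosis with neutrophils", "diagnosis": "psoriasis", "polarity": "support"},
    {"finding": "regular acanthosis", "diagnosis": "psoriasis", "polarity": "support"},
    {"finding": "spongiosis", "diagnosis": "psoriasis", "polarity": "refute"}
  ],
  "taught_pairs": [
    ["eosinophilic spongiosis", "allergic contact dermatitis"],
    ["serum crust", "nummular dermatitis"],
    ["parakeratosis with neutrophils", "psoriasis"]
  ]
}
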