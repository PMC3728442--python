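{
  "description": "Synthetic dermatopathology knowledge base covering the two study sub-domains: subepidermal vesicular dermatitides (SVD) and nodular and diffuse dermatitides (NDD).",
  "findings": [
    "blister",
    "eosinophils in blister cavity",
    "neutrophilic papillary microabscesses",
    "festooning of dermal papillae",
    "cell-poor subepidermal split",
    "dermal scarring with milia",
    "full-thickness epidermal necrosis",
    "subcorneal pustules with cocci",
    "annular vesicles at the rim",
    "sarcoidal naked granulomas",
    "palisaded granuloma with mucin",
    "necrobiosis with layered granulomas",
    "dense dermal neutrophilic infiltrate",
    "septal panniculitis",
    "caseating granulomas",
    "foamy histiocytes with bacilli",
    "amastigotes within histiocytes",
    "polarizable foreign material",
    "follicular rupture with sinus tracts",
    "palisaded granuloma with fibrin",
    "Touton giant cells"
  ],
  "diagnoses": [
    "bullous pemphigoid",
    "dermatitis herpetiformis",
    "epidermolysis bullosa acquisita",
    "porphyria cutanea tarda",
    "linear IgA bullous dermatosis",
    "cicatricial pemphigoid",
    "pemphigoid gestationis",
    "bullous systemic lupus erythematosus",
    "toxic epidermal necrolysis",
    "bullous impetigo",
    "friction blister",
    "bullous drug eruption",
    "sarcoidosis",
    "granuloma annulare",
    "necrobiosis lipoidica",
    "sweet syndrome",
    "erythema nodosum",
    "acne conglobata",
    "lupus vulgaris",
    "lepromatous leprosy",
    "cutaneous leishmaniasis",
    "foreign body granuloma",
    "rheumatoid nodule",
    "juvenile xanthogranuloma"
  ],
  "relations": [
    {"finding": "blister", "diagnosis": "bullous pemphigoid", "polarity": "support"},
    {"finding": "blister", "diagnosis": "pemphigoid gestationis", "polarity": "support"},
    {"finding": "eosinophils in blister cavity", "diagnosis": "bullous pemphigoid", "polarity": "support"},
    {"finding": "eosinophils in blister cavity", "diagnosis": "pemphigoid gestationis", "polarity": "support"},
    {"finding": "eosinophils in blister cavity", "diagnosis": "bullous drug eruption", "polarity": "support"},
    {"finding": "neutrophilic papillary microabscesses", "diagnosis": "dermatitis herpetiformis", "polarity": "support"},
    {"finding": "neutrophilic papillary microabscesses", "diagnosis": "linear IgA bullous dermatosis", "polarity": "support"},
    {"finding": "neutrophilic papillary microabscesses", "diagnosis": "bullous systemic lupus erythematosus", "polarity": "support"},
    {"finding": "festooning of dermal papillae", "diagnosis": "porphyria cutanea tarda", "polarity": "support"},
    {"finding": "cell-poor subepidermal split", "diagnosis": "porphyria cutanea tarda", "polarity": "support"},
    {"finding": "cell-poor subepidermal split", "diagnosis": "epidermolysis bullosa acquisita", "polarity": "support"},
    {"finding": "cell-poor subepidermal split", "diagnosis": "friction blister", "polarity": "support"},
    {"finding": "dermal scarring with milia", "diagnosis": "epidermolysis bullosa acquisita", "polarity": "support"},
    {"finding": "dermal scarring with milia", "diagnosis": "cicatricial pemphigoid", "polarity": "support"},
    {"finding": "full-thickness epidermal necrosis", "diagnosis": "toxic epidermal necrolysis", "polarity": "support"},
    {"finding": "full-thickness epidermal necrosis", "diagnosis": "bullous drug eruption", "polarity": "support"},
    {"finding": "subcorneal pustules with cocci", "diagnosis": "bullous impetigo", "polarity": "support"},
    {"finding": "annular vesicles at the rim", "diagnosis": "linear IgA bullous dermatosis", "polarity": "support"},
    {"finding": "eosinophils in blister cavity", "diagnosis": "dermatitis herpetiformis", "polarity": "refute"},
    {"finding": "sarcoidal naked granulomas", "diagnosis": "sarcoidosis", "polarity": "support"},
    {"finding": "palisaded granuloma with mucin", "diagnosis": "granuloma annulare", "polarity": "support"},
    {"finding": "necrobiosis with layered granulomas", "diagnosis": "necrobiosis lipoidica", "polarity": "support"},
    {"finding": "dense dermal neutrophilic infiltrate", "diagnosis": "sweet syndrome", "polarity": "support"},
    {"finding": "dense dermal neutrophilic infiltrate", "diagnosis": "acne conglobata", "polarity": "support"},
    {"finding": "septal panniculitis", "diagnosis": "erythema nodosum", "polarity": "support"},
    {"finding": "caseating granulomas", "diagnosis": "lupus vulgaris", "polarity": "support"},
    {"finding": "foamy histiocytes with bacilli", "diagnosis": "lepromatous leprosy", "polarity": "support"},
    {"finding": "amastigotes within histiocytes", "diagnosis": "cutaneous leishmaniasis", "polarity": "support"},
    {"finding": "polarizable foreign material", "diagnosis": "foreign body granuloma", "polarity": "support"},
    {"finding": "follicular rupture with sinus tracts", "diagnosis": "acne conglobata", "polarity": "support"},
    {"finding": "palisaded granuloma with fibrin", "diagnosis": "rheumatoid nodule", "polarity": "support"},
    {"finding": "Touton giant cells", "diagnosis": "juvenile xanthogranuloma", "polarity": "support"},
    {"finding": "sarcoidal naked granulomas", "diagnosis": "lupus vulgaris", "polarity": "refute"}
  ],
  "taught_pairs": [
    ["blister", "bullous pemphigoid"],
    ["neutrophilic papillary microabscesses", "dermatitis herpetiformis"],
    ["festooning of dermal papillae", "porphyria cutanea tarda"],
    ["dermal scarring with milia", "epidermolysis bullosa acquisita"],
    ["annular vesicles at the rim", "linear IgA bullous dermatosis"],
    ["sarcoidal naked granulomas", "sarcoidosis"],
    ["palisaded granuloma with mucin", "granuloma annulare"],
    ["septal panniculitis", "erythema nodosum"],
    ["follicular rupture with sinus tracts", "acne conglobata"]
  ]
}
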