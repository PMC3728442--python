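{
  "description": "Synthetic 40-case library (20 SVD + 20 NDD) with diagnosis multiplicities sized for the default study sequence: per sub-domain one diagnosis with 5 cases, one with 4, one with 2, and 9 singletons.",
  "cases": [
    {"case_id": "svd-01", "subdomain": "SVD", "acceptable_dx": ["bullous pemphigoid"], "true_findings": ["blister", "eosinophils in blister cavity"]},
    {"case_id": "svd-02", "subdomain": "SVD", "acceptable_dx": ["bullous pemphigoid"], "true_findings": ["blister"]},
    {"case_id": "svd-03", "subdomain": "SVD", "acceptable_dx": ["bullous pemphigoid"], "true_findings": ["blister", "eosinophils in blister cavity"]},
    {"case_id": "svd-04", "subdomain": "SVD", "acceptable_dx": ["bullous pemphigoid"], "true_findings": ["eosinophils in blister cavity", "blister"]},
    {"case_id": "svd-05", "subdomain": "SVD", "acceptable_dx": ["bullous pemphigoid"], "true_findings": ["blister"]},
    {"case_id": "svd-06", "subdomain": "SVD", "acceptable_dx": ["dermatitis herpetiformis"], "true_findings": ["neutrophilic papillary microabscesses"]},
    {"case_id": "svd-07", "subdomain": "SVD", "acceptable_dx": ["dermatitis herpetiformis"], "true_findings": ["neutrophilic papillary microabscesses", "blister"]},
    {"case_id": "svd-08", "subdomain": "SVD", "acceptable_dx": ["dermatitis herpetiformis"], "true_findings": ["neutrophilic papillary microabscesses"]},
    {"case_id": "svd-09", "subdomain": "SVD", "acceptable_dx": ["dermatitis herpetiformis"], "true_findings": ["neutrophilic papillary microabscesses"]},
    {"case_id": "svd-10", "subdomain": "SVD", "acceptable_dx": ["epidermolysis bullosa acquisita"], "true_findings": ["cell-poor subepidermal split", "dermal scarring with milia"]},
    {"case_id": "svd-11", "subdomain": "SVD", "acceptable_dx": ["epidermolysis bullosa acquisita"], "true_findings": ["cell-poor subepidermal split"]},
    {"case_id": "svd-12", "subdomain": "SVD", "acceptable_dx": ["porphyria cutanea tarda"], "true_findings": ["festooning of dermal papillae", "cell-poor subepidermal split"]},
    {"case_id": "svd-13", "subdomain": "SVD", "acceptable_dx": ["linear IgA bullous dermatosis"], "true_findings": ["annular vesicles at the rim", "neutrophilic papillary microabscesses"]},
    {"case_id": "svd-14", "subdomain": "SVD", "acceptable_dx": ["cicatricial pemphigoid"], "true_findings": ["dermal scarring with milia"]},
    {"case_id": "svd-15", "subdomain": "SVD", "acceptable_dx": ["pemphigoid gestationis"], "true_findings": ["blister", "eosinophils in blister cavity"]},
    {"case_id": "svd-16", "subdomain": "SVD", "acceptable_dx": ["bullous systemic lupus erythematosus"], "true_findings": ["neutrophilic papillary microabscesses"]},
    {"case_id": "svd-17", "subdomain": "SVD", "acceptable_dx": ["toxic epidermal necrolysis", "bullous drug eruption"], "true_findings": ["full-thickness epidermal necrosis", "eosinophils in blister cavity"]},
    {"case_id": "svd-18", "subdomain": "SVD", "acceptable_dx": ["bullous impetigo"], "true_findings": ["subcorneal pustules with cocci"]},
    {"case_id": "svd-19", "subdomain": "SVD", "acceptable_dx": ["friction blister"], "true_findings": ["cell-poor subepidermal split"]},
    {"case_id": "svd-20", "subdomain": "SVD", "acceptable_dx": ["bullous drug eruption"], "true_findings": ["eosinophils in blister cavity", "full-thickness epidermal necrosis"]},
    {"case_id": "ndd-01", "subdomain": "NDD", "acceptable_dx": ["sarcoidosis"], "true_findings": ["sarcoidal naked granulomas"]},
    {"case_id": "ndd-02", "subdomain": "NDD", "acceptable_dx": ["sarcoidosis"], "true_findings": ["sarcoidal naked granulomas"]},
    {"case_id": "ndd-03", "subdomain": "NDD", "acceptable_dx": ["sarcoidosis"], "true_findings": ["sarcoidal naked granulomas"]},
    {"case_id": "ndd-04", "subdomain": "NDD", "acceptable_dx": ["sarcoidosis"], "true_findings": ["sarcoidal naked granulomas"]},
    {"case_id": "ndd-05", "subdomain": "NDD", "acceptable_dx": ["sarcoidosis"], "true_findings": ["sarcoidal naked granulomas"]},
    {"case_id": "ndd-06", "subdomain": "NDD", "acceptable_dx": ["granuloma annulare"], "true_findings": ["palisaded granuloma with mucin"]},
    {"case_id": "ndd-07", "subdomain": "NDD", "acceptable_dx": ["granuloma annulare"], "true_findings": ["palisaded granuloma with mucin"]},
    {"case_id": "ndd-08", "subdomain": "NDD", "acceptable_dx": ["granuloma annulare"], "true_findings": ["palisaded granuloma with mucin"]},
    {"case_id": "ndd-09", "subdomain": "NDD", "acceptable_dx": ["granuloma annulare"], "true_findings": ["palisaded granuloma with mucin"]},
    {"case_id": "ndd-10", "subdomain": "NDD", "acceptable_dx": ["necrobiosis lipoidica"], "true_findings": ["necrobiosis with layered granulomas"]},
    {"case_id": "ndd-11", "subdomain": "NDD", "acceptable_dx": ["necrobiosis lipoidica"], "true_findings": ["necrobiosis with layered granulomas"]},
    {"case_id": "ndd-12", "subdomain": "NDD", "acceptable_dx": ["sweet syndrome"], "true_findings": ["dense dermal neutrophilic infiltrate"]},
    {"case_id": "ndd-13", "subdomain": "NDD", "acceptable_dx": ["erythema nodosum"], "true_findings": ["septal panniculitis"]},
    {"case_id": "ndd-14", "subdomain": "NDD", "acceptable_dx": ["acne conglobata"], "true_findings": ["follicular rupture with sinus tracts", "dense dermal neutrophilic infiltrate"]},
    {"case_id": "ndd-15", "subdomain": "NDD", "acceptable_dx": ["lupus vulgaris"], "true_findings": ["caseating granulomas"]},
    {"case_id": "ndd-16", "subdomain": "NDD", "acceptable_dx": ["lepromatous leprosy"], "true_findings": ["foamy histiocytes with bacilli"]},
    {"case_id": "ndd-17", "subdomain": "NDD", "acceptable_dx": ["cutaneous leishmaniasis"], "true_findings": ["amastigotes within histiocytes"]},
    {"case_id": "ndd-18", "subdomain": "NDD", "acceptable_dx": ["foreign body granuloma"], "true_findings": ["polarizable foreign material"]},
    {"case_id": "ndd-19", "subdomain": "NDD", "acceptable_dx": ["rheumatoid nodule"], "true_findings": ["palisaded granuloma with fibrin"]},
    {"case_id": "ndd-20", "subdomain": "NDD", "acceptable_dx": ["juvenile xanthogranuloma"], "true_findings": ["Touton giant cells"]}
  ]
}
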