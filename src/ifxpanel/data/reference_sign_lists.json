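{
  "version": "1.0",
  "description": "Curated per-genus strong-correlation sign lists (genus abundance vs 1/Ct expression proxy) reported for a mucosal-biopsy Crohn's disease cohort at baseline, stratified by eventual infliximab response. Responder-enriched genera: Parvimonas, Hungatella; non-responder-enriched genera: Negativibacillus, Faecalibacterium, Eubacterium_hallii_group, Blautia.",
  "responder_genera": ["Parvimonas", "Hungatella"],
  "nonresponder_genera": ["Negativibacillus", "Faecalibacterium", "Eubacterium_hallii_group", "Blautia"],
  "sign_lists": [
    {
      "genus": "Parvimonas",
      "stratum": "responders",
      "positive": ["CXCL8", "TLR6", "TLR9", "TNFSF14", "SELE"],
      "negative": ["CCL22", "IL18", "IL15", "CCR3", "CD40LG", "CSF1", "NOS2", "NR3C1", "CCL8", "CXCL2"]
    },
    {
      "genus": "Parvimonas",
      "stratum": "non_responders",
      "positive": ["CCR4", "CXCL8"],
      "negative": []
    },
    {
      "genus": "Hungatella",
      "stratum": "responders",
      "positive": ["CCR7", "CXCR2", "CXCL8", "TLR6", "TLR9", "TNFSF14", "SELE"],
      "negative": ["CCL22", "IL18", "IL15", "CCR3"]
    },
    {
      "genus": "Hungatella",
      "stratum": "non_responders",
      "positive": ["CCL8", "CCR3", "CD40LG", "CSF1", "CXCL2", "IL15", "IL18", "IL6R", "NOS2", "NR3C1", "CCR7", "TLR9", "CCR4", "CXCR2", "TNFSF14", "SELE", "CXCL8"],
      "negative": ["CCL22"]
    },
    {
      "genus": "Negativibacillus",
      "stratum": "responders",
      "positive": ["IL18", "IL15", "CCR3", "CD40LG", "CSF1", "NOS2", "NR3C1", "CCL8", "CXCL2"],
      "negative": ["CXCR2", "CXCL8", "TLR6", "TLR9", "TNFSF14"]
    },
    {
      "genus": "Negativibacillus",
      "stratum": "non_responders",
      "positive": [],
      "negative": ["CCR4", "CXCR2", "CCR7"]
    },
    {
      "genus": "Faecalibacterium",
      "stratum": "responders",
      "positive": ["IL6R", "CCL22", "IL15", "IL18", "CCR3"],
      "negative": ["CCR4", "CCR7", "CXCR2", "CXCL8", "TLR6", "TLR9", "TNFSF14", "SELE"]
    },
    {
      "genus": "Faecalibacterium",
      "stratum": "non_responders",
      "positive": [],
      "negative": ["TLR6", "CXCL8"]
    },
    {
      "genus": "Eubacterium_hallii_group",
      "stratum": "responders",
      "positive": ["CD40LG", "CSF1", "NOS2", "NR3C1", "CCL8", "CXCL2", "CCR9", "CCR7"],
      "negative": []
    },
    {
      "genus": "Eubacterium_hallii_group",
      "stratum": "non_responders",
      "positive": ["CCR4", "CXCR2"],
      "negative": ["CXCL8"]
    },
    {
      "genus": "Blautia",
      "stratum": "responders",
      "positive": ["IL18", "IL15", "CCR3", "CD40LG", "CSF1", "NOS2", "NR3C1", "CCL8", "CXCL2"],
      "negative": ["CXCR2", "CXCL8", "TLR6", "TLR9", "TNFSF14"]
    },
    {
      "genus": "Blautia",
      "stratum": "non_responders",
      "positive": [],
      "negative": ["CCR4", "CXCR2", "CCR7"]
    }
  ],
  "baseline_de_gene_counts": {
    "lower_in_nonresponders": 53,
    "higher_in_nonresponders": 7,
    "reported_total": 60
  },
  "reported_panel": {
    "up_in_responders": ["IL18", "CCR3", "CXCL8", "TLR6", "TLR9", "TNFSF14"],
    "down_in_responders": ["CCR4"]
  }
}
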