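{
  "type": "object",
  "required": [
    "tumor_id", "n_spots_total", "n_spots_used", "n_loci", "n_subclones",
    "subclones", "scope", "newick", "bootstrap", "invasion", "statistics",
    "preprocessing"
  ],
  "properties": {
    "tumor_id": {"type": "string"},
    "n_spots_total": {"type": "integer"},
    "n_spots_used": {"type": "integer"},
    "n_loci": {"type": "integer"},
    "n_subclones": {"type": "integer"},
    "newick": {"type": "string"},
    "subclones": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["subclone_id", "n_spots", "mutations", "member_spots"],
        "properties": {
          "subclone_id": {"type": "string"},
          "n_spots": {"type": "integer"},
          "mutations": {"type": "array"},
          "member_spots": {"type": "array"}
        }
      }
    },
    "bootstrap": {
      "type": "object",
      "required": ["n_replicates", "supports"],
      "properties": {
        "n_replicates": {"type": "integer"},
        "supports": {"type": "object"}
      }
    },
    "invasion": {
      "type": "object",
      "required": ["invading_subclones", "monophyletic", "multiclonal",
                   "n_events", "early_invasion", "per_event", "timing"],
      "properties": {
        "invading_subclones": {"type": "array"},
        "n_events": {"type": "integer"},
        "early_invasion": {"type": "boolean"},
        "per_event": {"type": "array"},
        "timing": {"type": "array"}
      }
    },
    "statistics": {
      "type": "object",
      "required": ["contiguity", "spatial_genetic_pearson",
                   "adjacent_subclone_distances"]
    },
    "preprocessing": {
      "type": "object",
      "required": ["excluded_spots", "admixed_spots", "n_homoplasy_flips", "audit"]
    }
  }
}
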