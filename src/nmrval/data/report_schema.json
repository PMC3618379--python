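{
 "$schema": "http://json-schema.org/draft-07/schema#",
 "title": "nmrval validation report",
 "type": "object",
 "required": ["entry", "ensemble", "residues", "distance_constraints",
              "dihedral_constraints", "rdc", "shifts", "rog"],
 "properties": {
  "entry": {
   "type": "object",
   "required": ["id", "generator", "thresholds", "summary"],
   "properties": {
    "id": {"type": "string"},
    "generator": {"type": "string"},
    "thresholds": {"type": "object"},
    "summary": {
     "type": "object",
     "required": ["n_residues", "rog_counts"],
     "properties": {
      "n_residues": {"type": "integer", "minimum": 0},
      "rog_counts": {
       "type": "object",
       "required": ["red", "orange", "green"],
       "additionalProperties": {"type": "integer", "minimum": 0}
      }
     }
    }
   }
  },
  "ensemble": {
   "type": "object",
   "required": ["n_models", "chains"],
   "properties": {
    "n_models": {"type": "integer", "minimum": 1},
    "representative_model": {"type": "integer"},
    "clusters": {
     "type": "array",
     "items": {
      "type": "object",
      "required": ["members", "representative"],
      "properties": {
       "members": {"type": "array", "items": {"type": "integer"}},
       "representative": {"type": "integer"}
      }
     }
    }
   }
  },
  "residues": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["chain", "resnum", "resname", "rog"],
    "properties": {
     "chain": {"type": "string"},
     "resnum": {"type": "integer"},
     "resname": {"type": "string"},
     "s2": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
     "worst_distance_violation_A": {"type": "number", "minimum": 0},
     "worst_dihedral_violation_deg": {"type": "number", "minimum": 0},
     "worst_abs_z": {"type": ["number", "null"]},
     "long_range_count": {"type": "integer", "minimum": 0},
     "near_aromatic": {"type": "boolean"},
     "rog": {"enum": ["red", "orange", "green"]}
    }
   }
  },
  "distance_constraints": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "n_models", "n_violated", "max_magnitude"],
    "properties": {
     "id": {"type": "string"},
     "range_class": {"enum": ["intra", "short", "medium", "long", null]},
     "n_models": {"type": "integer", "minimum": 1},
     "n_violated": {"type": "integer", "minimum": 0},
     "max_magnitude": {"type": "number", "minimum": 0},
     "mean_magnitude": {"type": "number", "minimum": 0},
     "per_model": {"type": "array"}
    }
   }
  },
  "dihedral_constraints": {"$ref": "#/properties/distance_constraints"},
  "rdc": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["medium", "convention", "models"],
    "properties": {
     "medium": {"type": "string"},
     "convention": {"enum": ["raw", "prescaled"]},
     "models": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["model", "tensor", "da_hz", "rhombicity", "rmsd_hz"],
       "properties": {
        "model": {"type": "integer"},
        "tensor": {"type": "array"},
        "da_hz": {"type": "number"},
        "rhombicity": {"type": "number"},
        "axes": {"type": "array"},
        "rmsd_hz": {"type": "number", "minimum": 0},
        "pearson_r": {"type": ["number", "null"]},
        "q_value": {"type": ["number", "null"], "minimum": 0},
        "degenerate": {"type": "boolean"}
       }
      }
     }
    }
   }
  },
  "shifts": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["offsets_ppm", "records"],
    "properties": {
     "offsets_ppm": {"type": "object"},
     "records": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["chain", "resnum", "atom", "nucleus_class",
                    "observed_ppm", "z", "outlier"],
       "properties": {
        "z": {"type": ["number", "null"]},
        "outlier": {"type": "boolean"},
        "color": {
         "type": ["array", "null"],
         "items": {"type": "integer", "minimum": 0, "maximum": 255}
        }
       }
      }
     }
    }
   }
  },
  "rog": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["chain", "resnum", "rog", "rationale"],
    "properties": {
     "rog": {"enum": ["red", "orange", "green"]},
     "rationale": {"type": "array", "items": {"type": "string"}}
    }
   }
  }
 }
}
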