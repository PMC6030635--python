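{
  "type": "object",
  "required": ["provenance", "stages"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package", "version", "seed", "config_sha256"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "config_sha256": {"type": "string"}
      }
    },
    "stages": {
      "type": "object",
      "properties": {
        "phantom": {
          "type": "object",
          "required": ["shape", "voxel_size_mm", "true_volumes_mm3"],
          "properties": {
            "shape": {"type": "array", "items": {"type": "integer"}},
            "voxel_size_mm": {"type": "number"},
            "mode": {"type": "string"},
            "true_volumes_mm3": {"type": "object"}
          }
        },
        "filter": {
          "type": "object",
          "required": ["despeckled_voxels", "diffusion_iterations"],
          "properties": {
            "despeckled_voxels": {"type": "integer"},
            "diffusion_iterations": {"type": "integer"},
            "stop_criterion": {"type": "number"}
          }
        },
        "segment": {
          "type": "object",
          "required": ["volumes_mm3", "enamel_dentine_ratio"],
          "properties": {
            "volumes_mm3": {"type": "object"},
            "enamel_dentine_ratio": {"type": "number"},
            "dice_vs_truth": {"type": "object"}
          }
        },
        "thickness": {
          "type": "object",
          "required": ["n_elements", "n_defined", "bin_width_mm", "modal_thickness_mm"],
          "properties": {
            "n_elements": {"type": "integer"},
            "n_defined": {"type": "integer"},
            "bin_width_mm": {"type": "number"},
            "modal_thickness_mm": {"type": "number"},
            "median_thickness_mm": {"type": "number"}
          }
        },
        "biomech": {
          "type": "object",
          "required": ["mode", "c_interval", "critical_load_n"],
          "properties": {
            "mode": {"type": "string"},
            "c_interval": {"type": "array", "items": {"type": "number"}},
            "critical_load_n": {"type": "array", "items": {"type": "number"}},
            "resistance_ratio_low_high": {"type": "array", "items": {"type": "number"}},
            "bite_force": {"type": "object"}
          }
        }
      }
    }
  }
}
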