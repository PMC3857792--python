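{
  "cdc": {
    "scale_id": "CDC",
    "max_points": 24,
    "points_per_item": [0, 1, 2],
    "items": {
      "mental_status": ["well and alert", "restless or irritable", "lethargic or unconscious"],
      "thirst": ["drinks normally", "thirsty/eager to drink", "unable to drink"],
      "heart_rate": ["normal", "increased", "tachycardia"],
      "pulse_quality": ["normal", "decreased", "weak or impalpable"],
      "breathing": ["normal", "fast", "deep"],
      "eyes": ["normal", "slightly sunken", "very sunken"],
      "tears": ["tears present", "decreased tears", "absent tears"],
      "mouth_tongue": ["moist", "dry", "very dry"],
      "skin_recoil": ["instant recoil", "recoil in < 2 seconds", "recoil in > 2 seconds"],
      "capillary_refill": ["normal", "prolonged", "minimal"],
      "extremities": ["warm", "cool", "cold, mottled, or cyanotic"],
      "urine_output": ["normal", "decreased", "minimal"]
    }
  },
  "who": {
    "scale_id": "WHO",
    "max_points": 4,
    "severe_cutpoint": 2,
    "items": {
      "who_mental": ["alert or restless", "lethargic or unconscious"],
      "who_eyes": ["normal", "sunken"],
      "who_thirst": ["drinks normally or thirsty/eager to drink", "not able to drink or drinking poorly"],
      "who_skin_pinch": ["goes back quickly or slowly", "goes back very slowly"]
    },
    "derive_from_cdc": {
      "who_mental": {"cdc_item": "mental_status", "positive_levels": [2]},
      "who_eyes": {"cdc_item": "eyes", "positive_levels": [1, 2], "strict_positive_levels": [2]},
      "who_thirst": {"cdc_item": "thirst", "positive_levels": [2]},
      "who_skin_pinch": {"cdc_item": "skin_recoil", "positive_levels": [2]}
    }
  },
  "cds": {
    "scale_id": "CDS",
    "max_points": 8,
    "items": {
      "general_appearance": ["normal", "thirsty, restless, or irritable", "lethargic or unconscious"],
      "eyes": ["normal", "slightly sunken", "very sunken"],
      "mucous_membranes": ["moist", "dry", "very dry"],
      "tears": ["tears present", "decreased tears", "absent tears"]
    },
    "derive_from_cdc": {
      "general_appearance": {"rule": "2 if mental_status==2 else 1 if (mental_status==1 or thirst>=1) else 0"},
      "eyes": {"cdc_item": "eyes"},
      "mucous_membranes": {"cdc_item": "mouth_tongue"},
      "tears": {"cdc_item": "tears"}
    }
  }
}
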