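{
  "rules": {
    "abdomen": ["abdomen", "bowel", "ileus", "gas", "stool", "fracture"],
    "ankle": ["ankle", "malleolus", "talus", "tibia", "fibula", "joint", "effusion", "swelling", "spur", "sprain", "fracture"],
    "calcaneus": ["calcaneus", "heel", "spur", "fracture"],
    "cervical spine": ["spine", "vertebra", "spondylosis", "alignment", "disc", "fracture"],
    "chest": ["chest", "lung", "rib", "clavicle", "heart", "pneumothorax", "effusion", "infiltration", "fracture"],
    "clavicle": ["clavicle", "fracture"],
    "coccyx": ["coccyx", "fracture"],
    "elbow": ["elbow", "olecranon", "radius", "ulna", "joint", "effusion", "fracture"],
    "femur": ["femur", "femoral", "shaft", "fracture"],
    "finger": ["finger", "phalanx", "joint", "fracture"],
    "foot": ["foot", "metatarsal", "phalanx", "hallux", "toe", "joint", "spur", "fracture"],
    "forearm": ["forearm", "radius", "ulna", "shaft", "fracture"],
    "hand": ["hand", "metacarpal", "phalanx", "joint", "fracture"],
    "hip": ["hip", "acetabulum", "trochanter", "joint", "fracture"],
    "humerus": ["humerus", "humeral", "shaft", "fracture"],
    "knee": ["knee", "patella", "femur", "tibia", "fibula", "genu", "varum", "valgum", "plateau", "joint", "effusion", "osteoarthritis", "fracture"],
    "lumbar spine": ["spine", "vertebra", "spondylosis", "scoliosis", "alignment", "disc", "fracture"],
    "leg": ["leg", "tibia", "fibula", "shaft", "fracture"],
    "lower limb": ["limb", "leg", "tibia", "fibula", "fracture"],
    "neck": ["neck", "trachea", "airway", "fracture"],
    "pelvis": ["pelvis", "ilium", "pubis", "ischium", "sacroiliac", "symphysis", "fracture"],
    "sacrum": ["sacrum", "sacroiliac", "fracture"],
    "scapula": ["scapula", "fracture"],
    "shoulder": ["shoulder", "clavicle", "acromion", "glenohumeral", "acromioclavicular", "joint", "dislocation", "effusion", "fracture"],
    "skull": ["skull", "cranium", "fracture"],
    "thoracic spine": ["spine", "vertebra", "compression", "alignment", "fracture"],
    "temporomandibular joint": ["temporomandibular", "condyle", "mandible", "joint", "fracture"],
    "wrist": ["wrist", "scaphoid", "carpal", "radius", "ulna", "styloid", "joint", "fracture"]
  },
  "bilateral_parts": [
    "chest", "abdomen", "pelvis", "skull", "neck",
    "cervical spine", "thoracic spine", "lumbar spine", "sacrum", "coccyx"
  ],
  "workarounds": [
    {"pattern": "(?i)\\bgenuvarum\\b", "replacement": "genu varum"},
    {"pattern": "(?i)\\bgenuvalgum\\b", "replacement": "genu valgum"},
    {"pattern": "(?i)^(.*?),\\s*(lt|rt)\\.?\\s*$", "replacement": "\\2 \\1"}
  ]
}
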