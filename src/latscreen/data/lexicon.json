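{
  "laterality_terms": {
    "lt": "left",
    "rt": "right",
    "left": "left",
    "right": "right",
    "bilateral": "bilateral",
    "both": "bilateral"
  },
  "view_terms": [
    "anteroposterior", "posteroanterior", "lateral", "lat", "oblique",
    "lordotic", "decubitus", "merchant", "axial", "skyline", "sunrise",
    "tangential", "odontoid", "swimmer", "townes", "waters", "standing",
    "erect", "supine", "flexion", "extension", "stress", "transthoracic",
    "view", "views", "ap", "pa", "kneeling"
  ],
  "stopwords": [
    "a", "an", "the", "of", "in", "on", "at", "to", "for", "with",
    "without", "and", "or", "no", "not", "is", "are", "was", "were",
    "be", "been", "being", "shows", "show", "showed", "seen", "noted",
    "there", "this", "that", "these", "those", "as", "by", "from",
    "about", "over", "under", "than", "more", "most", "other", "otherwise",
    "suggest", "suggested", "suspect", "suspected", "impression",
    "finding", "findings", "study", "studies", "film", "films"
  ],
  "order_part_synonyms": {
    "abdomen": ["abdomen"],
    "kub": ["abdomen"],
    "ankle": ["ankle"],
    "calcaneus": ["calcaneus"],
    "heel": ["calcaneus"],
    "cervical spine": ["cervical spine"],
    "c-spine": ["cervical spine"],
    "c spine": ["cervical spine"],
    "chest": ["chest"],
    "clavicle": ["clavicle"],
    "coccyx": ["coccyx"],
    "elbow": ["elbow"],
    "femur": ["femur"],
    "finger": ["finger"],
    "foot": ["foot"],
    "forearm": ["forearm"],
    "hand": ["hand"],
    "hip": ["hip"],
    "humerus": ["humerus"],
    "knee": ["knee"],
    "lumbar spine": ["lumbar spine"],
    "l-spine": ["lumbar spine"],
    "l spine": ["lumbar spine"],
    "leg": ["leg"],
    "lower limb": ["lower limb"],
    "neck": ["neck"],
    "pelvis": ["pelvis"],
    "sacrum": ["sacrum"],
    "scapula": ["scapula"],
    "shoulder": ["shoulder"],
    "skull": ["skull"],
    "thoracic spine": ["thoracic spine"],
    "t-spine": ["thoracic spine"],
    "t spine": ["thoracic spine"],
    "temporomandibular joint": ["temporomandibular joint"],
    "tmj": ["temporomandibular joint"],
    "wrist": ["wrist"],
    "l-s spine": ["lumbar spine", "sacrum"],
    "ls spine": ["lumbar spine", "sacrum"],
    "lumbosacral spine": ["lumbar spine", "sacrum"]
  },
  "heading_cues": [":\\s*$"]
}
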