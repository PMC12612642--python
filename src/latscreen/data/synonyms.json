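{
  "irregular_plurals": {
    "phalanges": "phalanx",
    "calcanei": "calcaneus",
    "vertebrae": "vertebra",
    "menisci": "meniscus",
    "femora": "femur",
    "humeri": "humerus",
    "radii": "radius",
    "ulnae": "ulna",
    "pelves": "pelvis",
    "halluces": "hallux",
    "foramina": "foramen",
    "feet": "foot"
  },
  "composites": {
    "genu varum": ["knee", "genu", "varum"],
    "genu valgum": ["knee", "genu", "valgum"],
    "genuvarum": ["knee", "genu", "varum"],
    "genuvalgum": ["knee", "genu", "valgum"],
    "tibia plateau": ["knee", "tibia", "plateau"],
    "tibial plateau": ["knee", "tibia", "plateau"],
    "hallux valgus": ["foot", "hallux"],
    "frozen shoulder": ["shoulder"]
  }
}
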