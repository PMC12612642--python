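{
 "abdomen": 0.011122,
 "ankle": 0.065392,
 "cervical spine": 0.015405,
 "calcaneus": 0.003963,
 "chest": 0.142419,
 "clavicle": 0.02282,
 "coccyx": 0.002813,
 "elbow": 0.038417,
 "femur": 0.033751,
 "finger": 0.006904,
 "foot": 0.065776,
 "forearm": 0.014446,
 "hand": 0.057083,
 "hip": 0.023523,
 "humerus": 0.014958,
 "knee": 0.130082,
 "lumbar spine": 0.039057,
 "leg": 0.037011,
 "lower limb": 0.002365,
 "neck": 0.000384,
 "pelvis": 0.063858,
 "sacrum": 0.034646,
 "scapula": 0.008054,
 "shoulder": 0.073127,
 "skull": 0.009013,
 "thoracic spine": 0.00799,
 "temporomandibular joint": 0.000192,
 "wrist": 0.075428
}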