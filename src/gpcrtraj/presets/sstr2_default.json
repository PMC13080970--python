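{
 "comment": "SSTR2 activation markers (author numbering of the 7T11-derived receptor model): TM5-TM7 CA distance 218-306, active < 19.0 A; TM6 outward-swing CA angle 262-269-81 (vertex 269), active > 45 deg.",
 "distance_atoms": [[218, "CA"], [306, "CA"]],
 "distance_threshold": 19.0,
 "angle_atoms": [[262, "CA"], [269, "CA"], [81, "CA"]],
 "angle_threshold": 45.0,
 "combine": "and"
}
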