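cause_raw,frequency
Stillborn,63
Predated lair deaths,5
Other lair deaths,97
Unweaned other deaths,6
Fishing (self-reported),142
Suffocation,21
Natural,26
Unknown,186
Accidental,1
Cancer,2
Boat collision,4
Violence,1
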