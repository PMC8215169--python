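{
  "FC3": ["C3", "C5", "C1"],
  "FC4": ["C4", "C2", "C6"],
  "C5": ["C3", "FC3", "CP3"],
  "C3": ["FC3", "C5", "C1", "CP3"],
  "C1": ["C3", "FC3", "CP3"],
  "C2": ["C4", "FC4", "CP4"],
  "C4": ["FC4", "C2", "C6", "CP4"],
  "C6": ["C4", "FC4", "CP4"],
  "CP3": ["C3", "C5", "C1"],
  "CP4": ["C4", "C2", "C6"]
}
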