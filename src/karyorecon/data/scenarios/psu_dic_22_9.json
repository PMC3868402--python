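{
  "description": "Replay of the proposed origin of the pseudodicentric involving chromosomes 22 and 9 in HEL: an unstable dic(9;22) formed by fusion of 9p24.3 and 22p12 undergoes BFB cycles between its centromeres, amplifying 9p and 22p material only, and the descendant is stabilised by centromere inactivation. Break positions are scripted (as fractions of the inter-centromeric span) so the replay keeps both 9p- and 22p-derived blocks.",
  "initial": {"type": "dicentric", "a": ["9", "p24.3"], "b": ["22", "p12"]},
  "cycles": 2,
  "follow": "left",
  "break_fractions": [0.9, 0.55],
  "stabilization": "centromere_inactivation",
  "params": {}
}
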