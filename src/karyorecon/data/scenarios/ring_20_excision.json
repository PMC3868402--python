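{
  "description": "Replay of the proposed origin of the ring chromosome 20 in HEL: an ancestral isodicentric section of 20q11.2 flanked by two 20 centromeres undergoes BFB cycles, then pericentromeric material around one centromere is excised and circularised into a centromere-bearing ring with no telomeric termini.",
  "initial": {"type": "isodicentric", "chrom": "20", "through_band": "q11.23"},
  "cycles": 2,
  "follow": "random",
  "stabilization": "ring_excision",
  "params": {"centromere": "20"}
}
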