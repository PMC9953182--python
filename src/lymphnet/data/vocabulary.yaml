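# Annotation vocabulary for the lymph-node model: compartments, species and
# process codes with the naming grammar used by every node identifier.
compartments:
  BL: blood
  DZ: dark zone
  GC: germinal center
  LN: lymph node
  LZ: light zone
  ME: medulla
  SCS: subcapsular sinus
  TIS: tissue
  TZ: T zone (paracortex)
species:
  AB: {name: antibody, compartments: [TIS]}
  AG: {name: antigen, compartments: [BL, TIS]}
  APC: {name: antigen-presenting cells, compartments: [TZ]}
  B: {name: B cell, compartments: [BL, TZ, GC, LZ]}
  B1: {name: B cell (activated), compartments: [LZ, DZ, GC]}
  B2: {name: B cell (plasma cell), compartments: [GC, TZ, ME, BL, TIS]}
  B3: {name: B cell (memory cell), compartments: [ME]}
  DC: {name: dendritic cells, compartments: [GC, LZ]}
  M: {name: macrophages, compartments: [DZ, GC, LZ, SCS, TIS, TZ]}
  T: {name: T cell, compartments: [BL, GC, LZ, TZ]}
processes:
  DIF: {name: differentiation, description: B cell differentiates to plasma B cell or memory B cell}
  ENC: {name: encounter, description: start of interaction between species, e.g. cell-cell communication or recognition of antigen}
  G1: {name: replication (G1 phase), description: G1 phase of cell replication}
  IN: {name: influx, description: interface to the environment that feeds species to the system}
  M: {name: replication (M phase), description: M phase of cell replication}
  OUT: {name: out-flux, description: interface to the environment that takes species from the system, also cell death}
  REG: {name: regeneration, description: a cell recovers and becomes active again}
  REL: {name: release, description: final step of the transport of an antibody by a B cell}
  SEP: {name: separation, description: end of interaction between species, e.g. cell-cell communication or recognition of antigen}
  TRA: {name: translocation, description: species moves from one compartment to another}
# State qualifiers usable inside place identifiers (reconstruction naming):
#   G1 - cell in the G1 phase of a replication motif
#   D  - degraded / spent material awaiting clearance
qualifiers:
  G1: G1-phase intermediate of a replication motif
  D: degraded or spent material
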