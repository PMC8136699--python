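# Germ-cell ladder: which germ-cell class occupies which stages of the
# seminiferous epithelium cycle, per cycle traversed by a cohort labeled at
# S-phase (preleptotene/leptotene, Pl/L, cycle ordinal 0). Transcribed from
# the published stage map; the only inter-species difference is the stage that
# holds Pl/L one hour after labeling (VII in A. cursor, IX elsewhere), which
# shifts the whole spermatocyte row. Rows tile stages I-XII without overlap;
# the final row stops at stage VII, where spermiation releases the cohort.
#
# stages: [first, last] inclusive span of Roman-numeral stages.
pl_l_at_VII:
  - {cell_class: A,    stages: [I, II],     cycle_ordinal: 0}
  - {cell_class: In,   stages: [III, IV],   cycle_ordinal: 0}
  - {cell_class: B,    stages: [V, V],      cycle_ordinal: 0}
  - {cell_class: Pl,   stages: [VI, VI],    cycle_ordinal: 0}
  - {cell_class: Pl/L, stages: [VII, VII],  cycle_ordinal: 0}
  - {cell_class: L,    stages: [VIII, IX],  cycle_ordinal: 0}
  - {cell_class: L/Z,  stages: [X, X],      cycle_ordinal: 0}
  - {cell_class: Z,    stages: [XI, XII],   cycle_ordinal: 0}
  - {cell_class: P,    stages: [I, X],      cycle_ordinal: 1}
  - {cell_class: D,    stages: [XI, XI],    cycle_ordinal: 1}
  - {cell_class: MII,  stages: [XII, XII],  cycle_ordinal: 1}
  - {cell_class: R,    stages: [I, VIII],   cycle_ordinal: 2}
  - {cell_class: E,    stages: [IX, XII],   cycle_ordinal: 2}
  - {cell_class: E,    stages: [I, VII],    cycle_ordinal: 3}

pl_l_at_IX:
  - {cell_class: A,    stages: [I, III],    cycle_ordinal: 0}
  - {cell_class: In,   stages: [IV, V],     cycle_ordinal: 0}
  - {cell_class: B,    stages: [VI, VI],    cycle_ordinal: 0}
  - {cell_class: Pl,   stages: [VII, VIII], cycle_ordinal: 0}
  - {cell_class: Pl/L, stages: [IX, IX],    cycle_ordinal: 0}
  - {cell_class: L,    stages: [X, X],      cycle_ordinal: 0}
  - {cell_class: L/Z,  stages: [XI, XI],    cycle_ordinal: 0}
  - {cell_class: Z,    stages: [XII, XII],  cycle_ordinal: 0}
  - {cell_class: P,    stages: [I, X],      cycle_ordinal: 1}
  - {cell_class: D,    stages: [XI, XI],    cycle_ordinal: 1}
  - {cell_class: MII,  stages: [XII, XII],  cycle_ordinal: 1}
  - {cell_class: R,    stages: [I, VIII],   cycle_ordinal: 2}
  - {cell_class: E,    stages: [IX, XII],   cycle_ordinal: 2}
  - {cell_class: E,    stages: [I, VII],    cycle_ordinal: 3}

species_variant:
  a_cursor: pl_l_at_VII
  a_montensis: pl_l_at_IX
  n_lasiurus: pl_l_at_IX
  o_nigripes: pl_l_at_IX
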