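{
  "description": "Curated Pfam domain families related to phage receptor-binding proteins, grouped by the terminus at which they typically occur.",
  "n_terminal": [
    "Phage_T7_tail",
    "Tail_spike_N",
    "Prophage_tail",
    "BppU_N",
    "Mtd_N",
    "Head_binding",
    "DUF3751",
    "End_N_terminal",
    "phage_tail_N",
    "Prophage_tailD1",
    "DUF2163",
    "Phage_fiber_2"
  ],
  "c_terminal": [
    "Lipase_GDSL_2",
    "Pectate_lyase_3",
    "gp37_C",
    "Beta_helix",
    "End_beta_propel",
    "End_tail_spike",
    "End_beta_barrel",
    "PhageP22-tail",
    "Phage_spike_2",
    "gp12-short_mid",
    "Collar",
    "Peptidase_S74",
    "Phage_fiber_C",
    "S_tail_recep_bd",
    "CBM_4_9",
    "DUF1983",
    "DUF3672"
  ]
}
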