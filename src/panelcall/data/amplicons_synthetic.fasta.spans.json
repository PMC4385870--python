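{
 "BRAF_V600": {
  "primer_fwd_span": [
   0,
   20
  ],
  "primer_rev_span": [
   130,
   150
  ],
  "ipc_identifier_span": [
   20,
   28
  ]
 },
 "EGFR_ex19": {
  "primer_fwd_span": [
   0,
   20
  ],
  "primer_rev_span": [
   130,
   150
  ],
  "ipc_identifier_span": [
   20,
   28
  ]
 },
 "EGFR_T790": {
  "primer_fwd_span": [
   0,
   20
  ],
  "primer_rev_span": [
   130,
   150
  ],
  "ipc_identifier_span": [
   20,
   28
  ]
 },
 "EGFR_L858": {
  "primer_fwd_span": [
   0,
   20
  ],
  "primer_rev_span": [
   130,
   150
  ],
  "ipc_identifier_span": [
   20,
   28
  ]
 },
 "KRAS_G12": {
  "primer_fwd_span": [
   0,
   20
  ],
  "primer_rev_span": [
   130,
   150
  ],
  "ipc_identifier_span": [
   20,
   28
  ]
 },
 "PIK3CA_E542": {
  "primer_fwd_span": [
   0,
   20
  ],
  "primer_rev_span": [
   130,
   150
  ],
  "ipc_identifier_span": [
   20,
   28
  ]
 },
 "PIK3CA_H1047": {
  "primer_fwd_span": [
   0,
   20
  ],
  "primer_rev_span": [
   130,
   150
  ],
  "ipc_identifier_span": [
   20,
   28
  ]
 }
}
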