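{
 "comment": "Default side-chain class table. TYR and PRO are counted hydrophobic, HIS charged, GLY polar-uncharged; all placements are conventions and the table may be replaced wholesale.",
 "classes": {
  "ALA": "hydrophobic", "VAL": "hydrophobic", "LEU": "hydrophobic",
  "ILE": "hydrophobic", "MET": "hydrophobic", "PHE": "hydrophobic",
  "TRP": "hydrophobic", "PRO": "hydrophobic", "TYR": "hydrophobic",
  "ASP": "charged", "GLU": "charged", "LYS": "charged",
  "ARG": "charged", "HIS": "charged",
  "SER": "polar_uncharged", "THR": "polar_uncharged", "ASN": "polar_uncharged",
  "GLN": "polar_uncharged", "CYS": "polar_uncharged", "GLY": "polar_uncharged"
 }
}
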