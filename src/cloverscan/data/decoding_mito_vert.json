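{
 "derivation": "Standard-code reverse-complement decoding (NCBI translation table 2); stop-decoding anticodons labelled Sup; specials override the plain map.",
 "disallowed": [],
 "domain": "mito",
 "map": {
  "AAA": "Phe",
  "AAC": "Val",
  "AAG": "Leu",
  "AAT": "Ile",
  "ACA": "Cys",
  "ACC": "Gly",
  "ACG": "Arg",
  "ACT": "Ser",
  "AGA": "Ser",
  "AGC": "Ala",
  "AGG": "Pro",
  "AGT": "Thr",
  "ATA": "Tyr",
  "ATC": "Asp",
  "ATG": "His",
  "ATT": "Asn",
  "CAA": "Leu",
  "CAC": "Val",
  "CAG": "Leu",
  "CAT": "Met",
  "CCA": "Trp",
  "CCC": "Gly",
  "CCG": "Arg",
  "CCT": "Sup",
  "CGA": "Ser",
  "CGC": "Ala",
  "CGG": "Pro",
  "CGT": "Thr",
  "CTA": "Sup",
  "CTC": "Glu",
  "CTG": "Gln",
  "CTT": "Lys",
  "GAA": "Phe",
  "GAC": "Val",
  "GAG": "Leu",
  "GAT": "Ile",
  "GCA": "Cys",
  "GCC": "Gly",
  "GCG": "Arg",
  "GCT": "Ser",
  "GGA": "Ser",
  "GGC": "Ala",
  "GGG": "Pro",
  "GGT": "Thr",
  "GTA": "Tyr",
  "GTC": "Asp",
  "GTG": "His",
  "GTT": "Asn",
  "TAA": "Leu",
  "TAC": "Val",
  "TAG": "Leu",
  "TAT": "Met",
  "TCA": "Trp",
  "TCC": "Gly",
  "TCG": "Arg",
  "TCT": "Sup",
  "TGA": "Ser",
  "TGC": "Ala",
  "TGG": "Pro",
  "TGT": "Thr",
  "TTA": "Sup",
  "TTC": "Glu",
  "TTG": "Gln",
  "TTT": "Lys"
 },
 "specials": {}
}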