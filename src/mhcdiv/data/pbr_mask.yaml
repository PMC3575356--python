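# Peptide-binding residues of the MHC class II beta-1 domain, as human-DRbeta
# position labels (antigen-contact positions of the human DR crystal
# structure, Brown et al. 1993), restricted to the exon-2 analysis window
# beta6..beta94.  Edit to reconcile site counts with an alternative mask.
#
# offset converts 1-based codon indices of the 267-bp window to beta labels:
# beta = codon + offset (codon 1 is beta6).
offset: 5
beta_positions:
  [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65, 67, 68, 70,
   71, 74, 78, 81, 82, 85, 86, 89, 90]
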