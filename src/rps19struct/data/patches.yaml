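# The five conserved RPS19 surface patches that contact 18S rRNA secondary
# structure elements in the assembled human small ribosomal subunit, version 1.
#
# protein_residues      : RPS19 residue numbers (canonical 1-145 numbering).
# rna_element           : 18S rRNA secondary-structure element name.
# rna_nucleotide_ranges : 18S rRNA nucleotide number intervals (closed).
version: 1
patches:
  I:
    rna_element: h42
    rna_nucleotide_ranges: [[1603, 1607], [1626, 1629]]
    protein_residues: [37, 38, 39, 43, 44, 45]
  II:
    rna_element: h41
    rna_nucleotide_ranges: [[1537, 1543], [1583, 1596]]
    protein_residues: [47, 52, 55, 56, 59, 62, 63, 67, 79, 80]
  III:
    rna_element: h42+h43
    rna_nucleotide_ranges: [[1653, 1656], [1664, 1666]]
    protein_residues: [84, 85, 86, 89, 91, 92]
  IV:
    rna_element: h41es10
    rna_nucleotide_ranges: [[1561, 1571]]
    protein_residues: [71, 72, 94, 96, 97, 98, 101, 102, 105, 120, 121]
  V:
    rna_element: h39es9
    rna_nucleotide_ranges: [[1414, 1430]]
    protein_residues: [2, 3, 4, 5, 6, 7, 8, 9, 65, 129, 132, 135]
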