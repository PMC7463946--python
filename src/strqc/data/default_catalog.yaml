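# Default locus catalog: common forensic autosomal STR loci plus amelogenin.
#
# Allele ranges cover the allelic ladders and published rare alleles of the
# widely used CE kits, compiled by the package maintainers; they are
# configuration, not ground truth — override with a project-specific catalog
# where needed.  The repeat structures given for TH01 and D5S818 are
# SYNTHETIC single-motif simplifications with invented (non-genomic) flank
# anchor sequences; they exist so that MPS fixtures can be generated and
# round-tripped without redistributing reference sequence data.
loci:
  - name: AMEL
    aliases: [Amelogenin, AMELOGENIN, AM]
    is_sex_marker: true
  - name: CSF1PO
    aliases: [HUMCSF1PO, CSF]
    repeat_unit_length: 4
    allele_range: [5, 17]
  - name: FGA
    aliases: [HUMFIBRA, FIBRA]
    repeat_unit_length: 4
    allele_range: [12, 52]
  - name: TH01
    aliases: [HUMTH01, TC11]
    repeat_unit_length: 4
    allele_range: [3, 14]
    expected_intermediates: [["9.3", 0.15]]
    repeat_structure:
      - {motif: AATG, min_count: 2, max_count: 15, counted: true}
    flank_5: GGGTATCTGGGCTCTAGGGAAC
    flank_3: CCTGTTCCTCCCTTATTTCCCT
  - name: TPOX
    aliases: [HUMTPOX]
    repeat_unit_length: 4
    allele_range: [4, 16]
  - name: vWA
    aliases: [VWA, HUMVWA, HUMVWFA31]
    repeat_unit_length: 4
    allele_range: [10, 25]
  - name: SE33
    aliases: [ACTBP2]
    repeat_unit_length: 4
    allele_range: [3, 49]
  - name: D1S1656
    repeat_unit_length: 4
    allele_range: [8, 21]
  - name: D2S441
    repeat_unit_length: 4
    allele_range: [8, 17]
  - name: D2S1338
    repeat_unit_length: 4
    allele_range: [15, 28]
  - name: D3S1358
    repeat_unit_length: 4
    allele_range: [8, 21]
  - name: D5S818
    repeat_unit_length: 4
    allele_range: [6, 18]
    repeat_structure:
      - {motif: AGAT, min_count: 2, max_count: 20, counted: true}
    flank_5: TTACACCCTAGGTAACTAACCT
    flank_3: ACCTATGGACCTGGAATCTCAG
  - name: D6S1043
    repeat_unit_length: 4
    allele_range: [8, 25]
  - name: D7S820
    repeat_unit_length: 4
    allele_range: [5, 16]
  - name: D8S1179
    repeat_unit_length: 4
    allele_range: [7, 20]
  - name: D10S1248
    repeat_unit_length: 4
    allele_range: [7, 19]
  - name: D12S391
    repeat_unit_length: 4
    allele_range: [14, 27]
  - name: D13S317
    repeat_unit_length: 4
    allele_range: [5, 17]
  - name: D16S539
    repeat_unit_length: 4
    allele_range: [4, 16]
  - name: D18S51
    repeat_unit_length: 4
    allele_range: [7, 40]
  - name: D19S433
    repeat_unit_length: 4
    allele_range: [9, 18]
  - name: D21S11
    repeat_unit_length: 4
    allele_range: [24, 41]
  - name: D22S1045
    repeat_unit_length: 3
    allele_range: [7, 20]
  - name: PentaD
    aliases: [Penta D]
    repeat_unit_length: 5
    allele_range: [2, 19]
  - name: PentaE
    aliases: [Penta E]
    repeat_unit_length: 5
    allele_range: [5, 26]
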