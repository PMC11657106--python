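# Gene loci for simulated cohorts. All genes are placed on chr21/chr22,
# which the simulator reserves (keeps flat 1/1) by default, so planted
# zygosity is never confounded by planted copy-number scars. These are NOT
# real gene coordinates; real analyses should supply a build-matched BED
# or YAML locus config.
loci:
  - {gene: BRCA1,   chromosome: chr21, start: 16000000, end: 16100000}
  - {gene: BRCA2,   chromosome: chr21, start: 19000000, end: 19100000}
  - {gene: ATM,     chromosome: chr21, start: 22000000, end: 22100000}
  - {gene: BARD1,   chromosome: chr21, start: 25000000, end: 25100000}
  - {gene: BRIP1,   chromosome: chr21, start: 28000000, end: 28100000}
  - {gene: CDK12,   chromosome: chr21, start: 31000000, end: 31100000}
  - {gene: CHEK1,   chromosome: chr21, start: 34000000, end: 34100000}
  - {gene: CHEK2,   chromosome: chr21, start: 37000000, end: 37100000}
  - {gene: FANCL,   chromosome: chr21, start: 40000000, end: 40100000}
  - {gene: PALB2,   chromosome: chr21, start: 43000000, end: 43100000}
  - {gene: PPP2R2A, chromosome: chr22, start: 20000000, end: 20100000}
  - {gene: RAD51B,  chromosome: chr22, start: 23000000, end: 23100000}
  - {gene: RAD51C,  chromosome: chr22, start: 26000000, end: 26100000}
  - {gene: RAD51D,  chromosome: chr22, start: 29000000, end: 29100000}
  - {gene: RAD54L,  chromosome: chr22, start: 32000000, end: 32100000}
  - {gene: TP53,    chromosome: chr22, start: 35000000, end: 35100000}
  - {gene: NF1,     chromosome: chr22, start: 38000000, end: 38100000}
  - {gene: RB1,     chromosome: chr22, start: 41000000, end: 41100000}
  - {gene: PIK3CA,  chromosome: chr22, start: 44000000, end: 44100000}
  - {gene: CCNE1,   chromosome: chr22, start: 47000000, end: 47100000}
  - {gene: PTEN,    chromosome: chr22, start: 49000000, end: 49100000}
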