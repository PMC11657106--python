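# hg19-like 22-autosome genome spec. Centromere intervals follow the hg19
# assembly gap annotation (approximate; scoring treats the build as config,
# never as code). Sex chromosomes are intentionally omitted: profiles may
# omit chromosomes, which then contribute zero to all scores.
chromosomes:
  - {name: chr1,  length: 249250621, cen_start: 121535434, cen_end: 124535434}
  - {name: chr2,  length: 243199373, cen_start: 92326171,  cen_end: 95326171}
  - {name: chr3,  length: 198022430, cen_start: 90504854,  cen_end: 93504854}
  - {name: chr4,  length: 191154276, cen_start: 49660117,  cen_end: 52660117}
  - {name: chr5,  length: 180915260, cen_start: 46405641,  cen_end: 49405641}
  - {name: chr6,  length: 171115067, cen_start: 58830166,  cen_end: 61830166}
  - {name: chr7,  length: 159138663, cen_start: 58054331,  cen_end: 61054331}
  - {name: chr8,  length: 146364022, cen_start: 43838887,  cen_end: 46838887}
  - {name: chr9,  length: 141213431, cen_start: 47367679,  cen_end: 50367679}
  - {name: chr10, length: 135534747, cen_start: 39254935,  cen_end: 42254935}
  - {name: chr11, length: 135006516, cen_start: 51644205,  cen_end: 54644205}
  - {name: chr12, length: 133851895, cen_start: 34856694,  cen_end: 37856694}
  - {name: chr13, length: 115169878, cen_start: 16000000,  cen_end: 19000000}
  - {name: chr14, length: 107349540, cen_start: 16000000,  cen_end: 19000000}
  - {name: chr15, length: 102531392, cen_start: 17000000,  cen_end: 20000000}
  - {name: chr16, length: 90354753,  cen_start: 35335801,  cen_end: 38335801}
  - {name: chr17, length: 81195210,  cen_start: 22263006,  cen_end: 25263006}
  - {name: chr18, length: 78077248,  cen_start: 15460898,  cen_end: 18460898}
  - {name: chr19, length: 59128983,  cen_start: 24681782,  cen_end: 27681782}
  - {name: chr20, length: 63025520,  cen_start: 26369569,  cen_end: 29369569}
  - {name: chr21, length: 48129895,  cen_start: 11288129,  cen_end: 14288129}
  - {name: chr22, length: 51304566,  cen_start: 13000000,  cen_end: 16000000}
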