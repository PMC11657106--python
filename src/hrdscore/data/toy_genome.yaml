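# Three-chromosome toy genome used throughout the test suite.
# Coordinates in bp, 0-based half-open; p arm = [0, cen_start), q arm = [cen_end, length).
chromosomes:
  - {name: chrA, length: 200000000, cen_start: 90000000, cen_end: 100000000}
  - {name: chrB, length: 150000000, cen_start: 70000000, cen_end: 75000000}
  - {name: chrC, length: 100000000, cen_start: 45000000, cen_end: 50000000}
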