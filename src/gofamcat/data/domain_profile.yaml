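# Default bHLH consensus profile.
#
# Columns are 0-based positions in a 60-column reference domain alignment.
# "residues" lists the residues accepted as consensus at that column;
# "tier" records whether the column is conserved at the 80% or 60% level.
# Sub-regions delimit the basic DNA-contacting stretch, the two helices and
# the loop; domain validation requires at least two of {basic, helix1,
# helix2} to be present and more than 60% of covered consensus columns to
# match.
ncols: 60
representative: ADKRAHHNALERRRRDKINNRFLELRSLLPSGSDKSSKASILDDAIEYIKELQKENQRLQ
subregions:
  - {name: basic, start: 0, end: 15}
  - {name: helix1, start: 15, end: 30}
  - {name: loop, start: 30, end: 38}
  - {name: helix2, start: 38, end: 58}
columns:
  - {col: 10, residues: [E], tier: 80}
  - {col: 11, residues: [R], tier: 80}
  - {col: 12, residues: [R], tier: 80}
  - {col: 13, residues: [R], tier: 60}
  - {col: 14, residues: [R], tier: 60}
  - {col: 16, residues: [K], tier: 60}
  - {col: 17, residues: [I], tier: 80}
  - {col: 18, residues: [N], tier: 80}
  - {col: 21, residues: [F], tier: 60}
  - {col: 23, residues: [E], tier: 60}
  - {col: 25, residues: [R], tier: 60}
  - {col: 27, residues: [L], tier: 60}
  - {col: 28, residues: [L], tier: 80}
  - {col: 29, residues: [P], tier: 60}
  - {col: 40, residues: [I], tier: 60}
  - {col: 43, residues: [D], tier: 60}
  - {col: 44, residues: [A], tier: 60}
  - {col: 46, residues: [E], tier: 60}
  - {col: 48, residues: [I], tier: 60}
  - {col: 51, residues: [L], tier: 80}
  - {col: 53, residues: [K], tier: 60}
  - {col: 54, residues: [E], tier: 60}
  - {col: 55, residues: [N], tier: 60}
  - {col: 57, residues: [R], tier: 60}
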