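# Editable example topology map for the deposited gamma-secretase
# cryo-EM models (e.g. PDB entry 5FN2).
#
# IMPORTANT: chain letters and transmembrane-helix residue ranges are
# APPROXIMATE starting values taken from common literature annotations of
# the complex. Depositions differ in chain assignment and modeled
# residues — verify every range against the entry you analyze (the
# `gsecens validate` subcommand reports which selections fail to resolve)
# and edit accordingly. The catalytic aspartates Asp257 (TM6) and Asp385
# (TM7) and the Arg583-Asp588 distal anchor of the nicastrin large lobe
# use author residue numbering.

membrane_normal: [0.0, 0.0, 1.0]

subunits:
  NCT:    {chain: A, ranges: [[1, 709]]}
  PS1:    {chain: B, ranges: [[1, 467]]}
  APH1A:  {chain: C, ranges: [[1, 265]]}
  PEN2:   {chain: D, ranges: [[1, 101]]}

helices:   # PS1 transmembrane helices (approximate boundaries — edit)
  TM1: {subunit: PS1, first: 78,  last: 98}
  TM2: {subunit: PS1, first: 133, last: 154}
  TM3: {subunit: PS1, first: 161, last: 183}
  TM4: {subunit: PS1, first: 195, last: 217}
  TM5: {subunit: PS1, first: 221, last: 241}
  TM6: {subunit: PS1, first: 244, last: 264}
  TM7: {subunit: PS1, first: 377, last: 397}
  TM8: {subunit: PS1, first: 406, last: 428}
  TM9: {subunit: PS1, first: 433, last: 455}

catalytic_pair:   # side-chain gamma carbons of the catalytic aspartates
  - {subunit: PS1, resid: 257, atom: CG}
  - {subunit: PS1, resid: 385, atom: CG}

nct_large_lobe: {subunit: NCT, first: 34, last: 240}   # approximate — edit

dih_anchors:   # four points of the ECD rotation dihedral
  - {subunit: NCT, resid: 672, atom: CA}    # intracellular end of NCT TM helix
  - {subunit: NCT, resid: 648, atom: CA}    # extracellular end of NCT TM helix
  - {subunit: NCT, first: 34, last: 240}    # centroid of the large lobe
  - {subunit: NCT, first: 583, last: 588}   # Arg583-Asp588 distal anchor

axis_endpoints:   # complex major axis: lower intracellular / upper extracellular
  - {subunit: PS1, first: 265, last: 288}   # intracellular TM6-TM7 loop region
  - {subunit: NCT, first: 240, last: 250}   # top of the NCT extracellular domain
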