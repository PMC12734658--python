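# Design matrix for the arylated saturated-heterocycle fragment library.
#
# Seven series, one per (scaffold, substitution-pattern) combination.  Ring
# positions count from the anchor group (ring N, sulfonyl S, or CF2 carbon) as
# position 1, so "head_position: 2 / aryl_position: 3" is a 2,3-disubstituted
# ring with the polar head alpha to the anchor.  Each block expands over its
# stereo (outer) and aryl (inner) options, in that order, and the frag_ids
# list names the resulting designs; FRAG numbering is editorial data, not
# derived.  Designs default to status "synthesized"; exceptions are listed
# under "status" at the end.
name: arylated-heterocycle-fragment-matrix
series:
  - name: 2,3-pyrrolidine
    scaffold: pyrrolidine
    head_position: 2
    aryl_position: 3
    blocks:
      - head: carboxylic_acid
        stereo: [cis]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG1, FRAG2]
      - head: primary_amide
        stereo: [cis]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG3, FRAG4]
      - head: primary_alcohol
        stereo: [cis]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG5, FRAG6]

  - name: 2,3-piperidine
    scaffold: piperidine
    head_position: 2
    aryl_position: 3
    blocks:
      - head: primary_amide
        stereo: [cis]
        aryl: [4-methoxyphenyl]
        frag_ids: [FRAG7]

  - name: 3,4-pyrrolidine
    scaffold: pyrrolidine
    head_position: 3
    aryl_position: 4
    blocks:
      - head: carboxylic_acid
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG8, FRAG9, FRAG10, FRAG11]
      - head: primary_amide
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG12, FRAG13, FRAG14, FRAG15]
      - head: primary_alcohol
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG16, FRAG17, FRAG18, FRAG19]

  - name: 3,4-piperidine
    scaffold: piperidine
    head_position: 3
    aryl_position: 4
    blocks:
      - head: carboxylic_acid
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG20, FRAG21, FRAG22, FRAG23]
      - head: primary_amide
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG24, FRAG25, FRAG26, FRAG27]
      - head: primary_alcohol
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG28, FRAG29, FRAG30, FRAG31]

  - name: 4,3-piperidine
    scaffold: piperidine
    head_position: 4
    aryl_position: 3
    blocks:
      - head: carboxylic_acid
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG32, FRAG33, FRAG34, FRAG35]
      - head: primary_amide
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG36, FRAG37, FRAG38, FRAG39]
      - head: primary_alcohol
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG40, FRAG41, FRAG42, FRAG43]
      - head: nitrile
        stereo: [cis]
        aryl: [4-methoxyphenyl, 4-fluorophenyl]
        frag_ids: [FRAG44, FRAG45]

  - name: 4,3-sulfone
    scaffold: cyclic_sulfone_6
    head_position: 4
    aryl_position: 3
    blocks:
      - head: carboxylic_acid
        stereo: [cis]
        aryl: [4-methoxyphenyl]
        frag_ids: [FRAG46]
      - head: primary_alcohol
        stereo: [cis]
        aryl: [4-methoxyphenyl]
        frag_ids: [FRAG47]

  - name: 4,3-difluorocyclohexane
    scaffold: gem_difluorocyclohexane
    head_position: 4
    aryl_position: 3
    blocks:
      - head: carboxylic_acid
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl]
        frag_ids: [FRAG48, FRAG49]
      - head: primary_alcohol
        stereo: [cis, trans]
        aryl: [4-methoxyphenyl]
        frag_ids: [FRAG50, FRAG51]

status:
  FRAG12:
    status: not_prepared
    reason: oxidative directing-group cleavage with the 4-methoxyphenyl group gave a spirocycle instead of the primary amide
  FRAG21:
    status: not_prepared
    reason: cis-fluoroarene not prioritized; inseparable cis/trans arylation mixture was epimerized to the trans analogue instead
  FRAG24:
    status: not_prepared
    reason: oxidative directing-group cleavage with the 4-methoxyphenyl group gave a spirolactam instead of the primary amide
  FRAG25:
    status: not_prepared
    reason: cis-fluoroarene not prioritized; inseparable cis/trans arylation mixture was epimerized to the trans analogue instead
  FRAG26:
    status: not_prepared
    reason: oxidative directing-group cleavage with the 4-methoxyphenyl group gave a spirolactam instead of the primary amide
  FRAG29:
    status: commercial
    reason: commercially available paroxetine substructure; not attempted
  FRAG31:
    status: commercial
    reason: commercially available paroxetine substructure; not attempted
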