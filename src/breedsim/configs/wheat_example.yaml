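# Generic wheat line-breeding program: one 7-year variety development
# cycle.  Founders are 50 inbred lines with 21 chromosomes of 1000
# segregating sites; a single additive trait (1000 QTL per chromosome) has
# broad-sense heritability 0.4 for a single-location evaluation.  Stages:
# 200 biparental crosses, 100 DH lines per F1, visual selection in head
# rows (modeled as H2=0.1 phenotyping), then preliminary, advanced (4
# locations) and elite (16 locations) yield trials down to one released
# variety.
founder:
  type: coalescent
  n_ind: 50
  n_chr: 21
  seg_sites: 1000
  inbred: true
  ploidy: 2
sim:
  nu: 2.6
  traits:
    - {type: A, n_qtl_per_chr: 1000, mean: 0.0, var: 1.0}
  var_e: {H2: 0.4}
stages:
  - {op: new_pop, out: Parents}
  - {op: rand_cross, in: Parents, out: F1, n_crosses: 200, n_progeny: 1}
  - {op: make_dh, in: F1, out: HDRW, n_dh: 100}
  - {op: set_pheno, in: HDRW, out: HDRW, H2: 0.1}
  - {op: select_within_fam, in: HDRW, out: PYT, n_per_fam: 5}
  - {op: set_pheno, in: PYT, out: PYT}
  - {op: select_ind, in: PYT, out: AYT, n: 100}
  - {op: set_pheno, in: AYT, out: AYT, reps: 4}
  - {op: select_ind, in: AYT, out: EYT, n: 10}
  - {op: set_pheno, in: EYT, out: EYT, reps: 16}
  - {op: select_ind, in: EYT, out: Variety, n: 1}
output:
  gv_stages: [Parents, F1, HDRW, PYT, AYT, EYT, Variety]
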