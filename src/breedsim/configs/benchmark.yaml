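# Recurrent-selection scalability benchmark: 100 generations, 1000 parents
# selected on phenotype each generation, 10,000 progeny per generation, for
# 1,000,000 meioses and 1,001,000 individuals in total.  The initial
# heritability is 0.3.  The genome here is reduced (1 chromosome, 100 loci)
# because the instantiated-individual count is genome-independent; the
# full-scale genome in the original benchmark is 10 chromosomes with 1000
# additive QTL each.
founder:
  type: quick
  n_ind: 1000
  n_chr: 1
  seg_sites: 100
  ploidy: 2
sim:
  nu: 1.0
  traits:
    - {type: A, n_qtl_per_chr: 100, mean: 0.0, var: 1.0}
  var_e: {H2: 0.3}
stages:
  - {op: new_pop, out: Pop}
  - {op: set_pheno, in: Pop, out: Pop}
  - op: repeat
    times: 100
    stages:
      - {op: select_ind, in: Pop, out: Parents, n: 1000, use: pheno}
      - {op: rand_cross, in: Parents, out: Pop, n_crosses: 10000, n_progeny: 1}
      - {op: set_pheno, in: Pop, out: Pop}
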