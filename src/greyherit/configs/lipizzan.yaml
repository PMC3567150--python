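# Study parameterisation of the four Grey-horse traits (trait units:
# melanoma grade 0-5, grey level L* 0-100, vitiligo and speckling grade 0-3).
# Variances are squared trait units; beta_age is per year of age; greying is
# measured on young horses (<= 84 months), the other traits on adults
# (>= 84 months).  p_g / p_a are the per-dataset founder allele frequencies
# (G of STX17 in 0.85-0.89, A of ASIP ~0.51).
traits:
  melanoma:
    v_poly: 0.19
    v_pe: 0.27
    v_e: 0.39
    alpha_stx17: -0.85
    asip_a: 0.19
    asip_d: 0.0
    beta_age: 0.11
    age_window: old
    scale: [0.0, 5.0]
    scale_step: 0.5
    p_g: 0.85
    p_a: 0.51
  greying:
    v_poly: 99.19
    v_pe: 5.06
    v_e: 32.66
    alpha_stx17: -13.78
    beta_age: 5.88
    age_window: young
    scale: [0.0, 100.0]
    p_g: 0.885
    p_a: 0.51
  vitiligo:
    v_poly: 0.29
    v_pe: 0.0
    v_e: 0.26
    alpha_stx17: -0.82
    beta_age: 0.06
    age_window: old
    scale: [0.0, 3.0]
    scale_step: 1.0
    p_g: 0.86
    p_a: 0.51
  speckling:
    v_poly: 0.09
    v_pe: 0.10
    v_e: 0.19
    alpha_stx17: 1.36
    beta_age: 0.02
    age_window: old
    scale: [0.0, 3.0]
    scale_step: 1.0
    p_g: 0.85
    p_a: 0.51

design:
  n_founders: 150
  n_generations: 5
  offspring_per_generation: 240
  mean_offspring_per_sire: 5.97
  mean_offspring_per_dam: 2.26
  n_studs: 6
  years: [1999, 2000, 2001, 2002, 2003, 2004, 2005, 2006, 2007]
  mean_records_per_animal: 3.0
  seed: 0
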