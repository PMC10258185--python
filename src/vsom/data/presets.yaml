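# Published parameter sets for the three spatial-orientation models.
# "untuned" are the literature values of the original model publications;
# "perception" and "sickness" are the re-tuned sets.
svm:
  untuned:
    tau_ssc: 5.7
    tau_lp_xy: 5.0
    tau_lp_z: 5.0
    K_ac_xy: 1.0
    K_ac_z: 1.0
    K_gc_xy: 5.0
    K_gc_z: 5.0
    K_wc: 2.28
  perception:
    tau_ssc: 5.7
    tau_lp_xy: 1.23
    tau_lp_z: 1.23
    K_ac_xy: 0.005
    K_ac_z: 0.005
    K_gc_xy: 1.88
    K_gc_z: 1.88
    K_wc: 2.28
  sickness:
    tau_ssc: 5.7
    tau_lp_xy: 15.0
    tau_lp_z: 5.13
    K_ac_xy: 1.2
    K_ac_z: 0.78
    K_gc_xy: 3.26
    K_gc_z: 5.88
    K_wc: 2.28
msom:
  untuned:
    tau_ssc: 5.7
    K_a: -4.0
    K_f: 4.0
    K_fw: 8.0
    K_w: 8.0
    K_wf: 1.0
  perception:
    tau_ssc: 5.7
    K_a: -3.2
    K_f: 15.4
    K_fw: 0.0
    K_w: 2.28
    K_wf: 1.0
  sickness:
    tau_ssc: 5.7
    K_a: -7.2
    K_f: 0.004
    K_fw: 8.4
    K_w: 11.2
    K_wf: 1.0
pfm:
  untuned:
    tau_ssc: 4.0
    sigma_c: 10.0
    sigma_a: 5.0
    sigma_w: 30.0
  perception:
    tau_ssc: 5.7
    sigma_c: 10.0
    sigma_a: 0.5
    sigma_w: 26.0
  sickness:
    tau_ssc: 5.7
    sigma_c: 10.0
    sigma_a: 1.5
    sigma_w: 26.0
# Conflict weights of the integrated sickness proxy, found by fitting the
# empirical sickness frequency sensitivities.  One conflict per model.
sickness_weights:
  svm: {c_g: 1.0, c_a: 0.0, c_w: 0.0}
  msom: {c_o: 1.0, c_oa: 0.0, c_w: 0.0}
  pfm: {c_w: 1.0}
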