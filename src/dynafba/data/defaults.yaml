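# Packaged defaults: benchmark laboratory wine fermentation
step: 0.5
temperature: 28.0
sugar_threshold: 3.0
N_exhaust: 1.0
max_time: 1000.0
params:
  sugar:
    vmax_ref_glc: 4.2
    vmax_ref_fru: 4.0
    Kg: 1.0
    Kf: 2.0
    Kig_f: 20.0
    Kif_g: 10.0
    Ki_eth: 150.0
    Ea: 60000.0
    T_ref: 28.0
  nitrogen:
    vmax_N: 35.0
    K_N: 30.0
  maintenance:
    m0: 1.2
    a_eth: 0.01
    E_thr: 31.6
    a_T: 0.12
    T_thr: 30.0
    a_sluggish: 1.0
    N_sluggish: 140.0
    legacy_value: 1.0
  carbohydrate:
    c_min: 0.25
    c_max: 0.45
    k_c: 2.0
composition:
  protein: 0.4
  carbohydrate: 0.35
  lipid: 0.08
  rna: 0.12
  dna: 0.05
  atp_cost: 60.0
nitrogen_compounds:
- species: nh4
  mg_n_per_mmol: 14.0
- species: aa
  mg_n_per_mmol: 14.0
initial:
  temperature: 28.0
  biomass: 0.1
  concentrations:
    glc: 116.5
    fru: 116.5
    nh4: 120.0
    aa: 180.0
    etoh: 0.0
    glyc: 0.0
    ac: 0.0
    succ: 0.0
    co2: 0.0
    actn: 0.0
    btd: 0.0
    sterol_e: 0.05
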