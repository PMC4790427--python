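pools:
- name: glc_plasma
  compartment: input
  n_carbons: 6
  concentration: 0.0
  is_input: true
  input_labeled_positions:
  - 1
  - 6
- name: glc
  compartment: shared
  n_carbons: 6
  concentration: 4.0
  bond_breaks:
  - 3
- name: pyr_n
  compartment: neuronal
  n_carbons: 3
  concentration: 0.1
- name: pyr_g
  compartment: glial
  n_carbons: 3
  concentration: 0.1
- name: lac
  compartment: shared
  n_carbons: 3
  concentration: 1.0
- name: co2
  compartment: shared
  n_carbons: 1
  concentration: 12.0
- name: accoa_n
  compartment: neuronal
  n_carbons: 2
  concentration: 0.1
- name: og_n
  compartment: neuronal
  n_carbons: 5
  concentration: 0.2
- name: glu_n
  compartment: neuronal
  n_carbons: 5
  concentration: 7.5600000000000005
- name: oaa_n
  compartment: neuronal
  n_carbons: 4
  concentration: 0.1
- name: asp_n
  compartment: neuronal
  n_carbons: 4
  concentration: 1.5
- name: accoa_g
  compartment: glial
  n_carbons: 2
  concentration: 0.1
- name: og_g
  compartment: glial
  n_carbons: 5
  concentration: 0.1
- name: glu_g
  compartment: glial
  n_carbons: 5
  concentration: 0.8399999999999999
- name: gln_g
  compartment: glial
  n_carbons: 5
  concentration: 4.3
- name: oaa_g
  compartment: glial
  n_carbons: 4
  concentration: 0.1
- name: asp_g
  compartment: glial
  n_carbons: 4
  concentration: 1.0
reactions:
- name: glc_transport
  flux_label: cmr_glc_ox
  substrates:
  - glc_plasma
  products:
  - pool: glc
    atom_maps:
    - 1: glc_plasma.1
      2: glc_plasma.2
      3: glc_plasma.3
      4: glc_plasma.4
      5: glc_plasma.5
      6: glc_plasma.6
- name: glycolysis_n
  flux_label: vpdh_n
  substrates:
  - glc
  substrate_stoich:
    glc: 0.5
  products:
  - pool: pyr_n
    atom_maps:
    - 1: glc.3
      2: glc.2
      3: glc.1
    - 1: glc.4
      2: glc.5
      3: glc.6
- name: glycolysis_g
  flux_label: vgly_g
  substrates:
  - glc
  substrate_stoich:
    glc: 0.5
  products:
  - pool: pyr_g
    atom_maps:
    - 1: glc.3
      2: glc.2
      3: glc.1
    - 1: glc.4
      2: glc.5
      3: glc.6
- name: ldh_n_fwd
  flux_label: v_ldh
  substrates:
  - pyr_n
  products:
  - pool: lac
    atom_maps:
    - 1: pyr_n.1
      2: pyr_n.2
      3: pyr_n.3
- name: ldh_n_rev
  flux_label: v_ldh
  substrates:
  - lac
  products:
  - pool: pyr_n
    atom_maps:
    - 1: lac.1
      2: lac.2
      3: lac.3
- name: ldh_g_fwd
  flux_label: v_ldh
  substrates:
  - pyr_g
  products:
  - pool: lac
    atom_maps:
    - 1: pyr_g.1
      2: pyr_g.2
      3: pyr_g.3
- name: ldh_g_rev
  flux_label: v_ldh
  substrates:
  - lac
  products:
  - pool: pyr_g
    atom_maps:
    - 1: lac.1
      2: lac.2
      3: lac.3
- name: lac_in
  flux_label: vin
  substrates: []
  products:
  - pool: lac
    atom_maps:
    - 1: unlabeled
      2: unlabeled
      3: unlabeled
- name: lac_out
  flux_label: vout
  substrates:
  - lac
  products: []
- name: pdh_n
  flux_label: vpdh_n
  substrates:
  - pyr_n
  products:
  - pool: accoa_n
    atom_maps:
    - 1: pyr_n.2
      2: pyr_n.3
  - pool: co2
    atom_maps:
    - 1: pyr_n.1
- name: pdh_g
  flux_label: vg
  substrates:
  - pyr_g
  products:
  - pool: accoa_g
    atom_maps:
    - 1: pyr_g.2
      2: pyr_g.3
  - pool: co2
    atom_maps:
    - 1: pyr_g.1
- name: accoa_g_dil_in
  flux_label: vdil
  substrates: []
  products:
  - pool: accoa_g
    atom_maps:
    - 1: unlabeled
      2: unlabeled
- name: accoa_g_dil_out
  flux_label: vdil_out
  substrates:
  - accoa_g
  products: []
- name: pc
  flux_label: vpc
  substrates:
  - pyr_g
  - co2
  products:
  - pool: oaa_g
    atom_maps:
    - 1: pyr_g.1
      2: pyr_g.2
      3: pyr_g.3
      4: co2.1
- name: cs_n
  flux_label: vpdh_n
  substrates:
  - oaa_n
  - accoa_n
  products:
  - pool: og_n
    atom_maps:
    - 1: oaa_n.4
      2: oaa_n.3
      3: oaa_n.2
      4: accoa_n.2
      5: accoa_n.1
  - pool: co2
    atom_maps:
    - 1: oaa_n.1
- name: cs_g
  flux_label: vtca_g
  substrates:
  - oaa_g
  - accoa_g
  products:
  - pool: og_g
    atom_maps:
    - 1: oaa_g.4
      2: oaa_g.3
      3: oaa_g.2
      4: accoa_g.2
      5: accoa_g.1
  - pool: co2
    atom_maps:
    - 1: oaa_g.1
- name: ogdh_n
  flux_label: vpdh_n
  substrates:
  - og_n
  products:
  - pool: oaa_n
    atom_maps:
    - 1: og_n.2
      2: og_n.3
      3: og_n.4
      4: og_n.5
    - 1: og_n.5
      2: og_n.4
      3: og_n.3
      4: og_n.2
  - pool: co2
    atom_maps:
    - 1: og_n.1
- name: ogdh_g
  flux_label: vogdh_g
  substrates:
  - og_g
  products:
  - pool: oaa_g
    atom_maps:
    - 1: og_g.2
      2: og_g.3
      3: og_g.4
      4: og_g.5
    - 1: og_g.5
      2: og_g.4
      3: og_g.3
      4: og_g.2
  - pool: co2
    atom_maps:
    - 1: og_g.1
- name: x_og_glu_n_fwd
  flux_label: vx
  substrates:
  - og_n
  products:
  - pool: glu_n
    atom_maps:
    - 1: og_n.1
      2: og_n.2
      3: og_n.3
      4: og_n.4
      5: og_n.5
- name: x_og_glu_n_rev
  flux_label: vx
  substrates:
  - glu_n
  products:
  - pool: og_n
    atom_maps:
    - 1: glu_n.1
      2: glu_n.2
      3: glu_n.3
      4: glu_n.4
      5: glu_n.5
- name: x_og_glu_g_fwd
  flux_label: vx_glu_g_fwd
  substrates:
  - og_g
  products:
  - pool: glu_g
    atom_maps:
    - 1: og_g.1
      2: og_g.2
      3: og_g.3
      4: og_g.4
      5: og_g.5
- name: x_og_glu_g_rev
  flux_label: vx
  substrates:
  - glu_g
  products:
  - pool: og_g
    atom_maps:
    - 1: glu_g.1
      2: glu_g.2
      3: glu_g.3
      4: glu_g.4
      5: glu_g.5
- name: x_oaa_asp_n_fwd
  flux_label: vx
  substrates:
  - oaa_n
  products:
  - pool: asp_n
    atom_maps:
    - 1: oaa_n.1
      2: oaa_n.2
      3: oaa_n.3
      4: oaa_n.4
- name: x_oaa_asp_n_rev
  flux_label: vx
  substrates:
  - asp_n
  products:
  - pool: oaa_n
    atom_maps:
    - 1: asp_n.1
      2: asp_n.2
      3: asp_n.3
      4: asp_n.4
- name: x_oaa_asp_g_fwd
  flux_label: vx
  substrates:
  - oaa_g
  products:
  - pool: asp_g
    atom_maps:
    - 1: oaa_g.1
      2: oaa_g.2
      3: oaa_g.3
      4: oaa_g.4
- name: x_oaa_asp_g_rev
  flux_label: vx
  substrates:
  - asp_g
  products:
  - pool: oaa_g
    atom_maps:
    - 1: asp_g.1
      2: asp_g.2
      3: asp_g.3
      4: asp_g.4
- name: nt_release
  flux_label: vnt
  substrates:
  - glu_n
  products:
  - pool: glu_g
    atom_maps:
    - 1: glu_n.1
      2: glu_n.2
      3: glu_n.3
      4: glu_n.4
      5: glu_n.5
- name: gln_synthetase
  flux_label: vsyn
  substrates:
  - glu_g
  products:
  - pool: gln_g
    atom_maps:
    - 1: glu_g.1
      2: glu_g.2
      3: glu_g.3
      4: glu_g.4
      5: glu_g.5
- name: nt_return
  flux_label: vnt
  substrates:
  - gln_g
  products:
  - pool: glu_n
    atom_maps:
    - 1: gln_g.1
      2: gln_g.2
      3: gln_g.3
      4: gln_g.4
      5: gln_g.5
- name: gln_efflux
  flux_label: vefflux
  substrates:
  - gln_g
  products: []
- name: co2_efflux
  flux_label: vco2_out
  substrates:
  - co2
  products: []
measured_pools:
  glu:
  - glu_n
  - glu_g
  gln:
  - gln_g
constants:
  v_ldh: 1.0
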