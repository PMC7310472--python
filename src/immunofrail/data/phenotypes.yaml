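phenotypes:
- name: beads
  tube: trucount
  parent: null
  predicates:
  - channel: CD3
    relation: bright
  - channel: CD19
    relation: bright
- name: leukocytes
  tube: trucount
  parent: null
  predicates:
  - channel: CD45
    relation: positive
- name: neutrophils
  tube: trucount
  parent: leukocytes
  predicates:
  - channel: SSC
    relation: bright
  - channel: CD45
    relation: dim
- name: monocytes
  tube: trucount
  parent: leukocytes
  predicates:
  - channel: SSC
    relation: dim
  - channel: CD45
    relation: dim
  - channel: CD3
    relation: negative
  - channel: CD19
    relation: negative
- name: cd16neg_monocytes
  tube: trucount
  parent: monocytes
  predicates:
  - channel: CD16
    relation: negative
- name: cd16pos_monocytes
  tube: trucount
  parent: monocytes
  predicates:
  - channel: CD16
    relation: positive
- name: lymphocytes
  tube: trucount
  parent: leukocytes
  predicates:
  - channel: SSC
    relation: negative
  - channel: CD45
    relation: bright
- name: t_cells
  tube: trucount
  parent: lymphocytes
  predicates:
  - channel: CD3
    relation: positive
- name: cd56pos_t_cells
  tube: trucount
  parent: t_cells
  predicates:
  - channel: CD56
    relation: positive
- name: cd4_t_cells
  tube: trucount
  parent: t_cells
  predicates:
  - channel: CD56
    relation: negative
  - channel: CD4
    relation: positive
- name: cd8_t_cells
  tube: trucount
  parent: t_cells
  predicates:
  - channel: CD56
    relation: negative
  - channel: CD8
    relation: positive
- name: b_cells
  tube: trucount
  parent: lymphocytes
  predicates:
  - channel: CD3
    relation: negative
  - channel: CD19
    relation: positive
- name: transitional_b_cells
  tube: trucount
  parent: b_cells
  predicates:
  - channel: CD38
    relation: bright
  - channel: CD27
    relation: negative
- name: naive_b_cells
  tube: trucount
  parent: b_cells
  predicates:
  - channel: CD38
    relation: dim
  - channel: CD27
    relation: negative
- name: memory_b_cells
  tube: trucount
  parent: b_cells
  predicates:
  - channel: CD38
    relation: dim
  - channel: CD27
    relation: positive
- name: nk_cells
  tube: trucount
  parent: lymphocytes
  predicates:
  - channel: CD3
    relation: negative
  - channel: CD19
    relation: negative
- name: nk_cd56bright_cd16neg
  tube: trucount
  parent: nk_cells
  predicates:
  - channel: CD56
    relation: bright
  - channel: CD16
    relation: negative
- name: nk_cd56dim_cd16pos
  tube: trucount
  parent: nk_cells
  predicates:
  - channel: CD56
    relation: dim
  - channel: CD16
    relation: positive
- name: nk_cd56dim_cd16neg
  tube: trucount
  parent: nk_cells
  predicates:
  - channel: CD56
    relation: dim
  - channel: CD16
    relation: negative
- name: nk_cd56neg_cd16pos
  tube: trucount
  parent: nk_cells
  predicates:
  - channel: CD56
    relation: negative
  - channel: CD16
    relation: positive
- name: t_cells
  tube: falcon
  parent: null
  predicates:
  - channel: CD3
    relation: positive
- name: cd4_t_cells
  tube: falcon
  parent: t_cells
  predicates:
  - channel: CD4
    relation: bright
  - channel: CD8
    relation: negative
- name: cd8_t_cells
  tube: falcon
  parent: t_cells
  predicates:
  - channel: CD8
    relation: bright
  - channel: CD4
    relation: negative
- name: cd4_naive
  tube: falcon
  parent: cd4_t_cells
  predicates:
  - channel: CCR7
    relation: positive
  - channel: CD45RA
    relation: positive
- name: cd4_cm
  tube: falcon
  parent: cd4_t_cells
  predicates:
  - channel: CCR7
    relation: positive
  - channel: CD45RA
    relation: negative
- name: cd4_tem
  tube: falcon
  parent: cd4_t_cells
  predicates:
  - channel: CCR7
    relation: negative
  - channel: CD45RA
    relation: negative
- name: cd4_tem_early
  tube: falcon
  parent: cd4_tem
  predicates:
  - channel: CD27
    relation: positive
  - channel: CD28
    relation: positive
- name: cd4_tem_late
  tube: falcon
  parent: cd4_tem
  predicates:
  - channel: CD27
    relation: negative
  - channel: CD28
    relation: negative
- name: cd4_temra
  tube: falcon
  parent: cd4_t_cells
  predicates:
  - channel: CCR7
    relation: negative
  - channel: CD45RA
    relation: positive
- name: cd4_temra_early
  tube: falcon
  parent: cd4_temra
  predicates:
  - channel: CD27
    relation: positive
  - channel: CD28
    relation: positive
- name: cd4_temra_late
  tube: falcon
  parent: cd4_temra
  predicates:
  - channel: CD27
    relation: negative
  - channel: CD28
    relation: negative
- name: cd8_naive
  tube: falcon
  parent: cd8_t_cells
  predicates:
  - channel: CCR7
    relation: positive
  - channel: CD45RA
    relation: positive
- name: cd8_cm
  tube: falcon
  parent: cd8_t_cells
  predicates:
  - channel: CCR7
    relation: positive
  - channel: CD45RA
    relation: negative
- name: cd8_tem
  tube: falcon
  parent: cd8_t_cells
  predicates:
  - channel: CCR7
    relation: negative
  - channel: CD45RA
    relation: negative
- name: cd8_tem_early
  tube: falcon
  parent: cd8_tem
  predicates:
  - channel: CD27
    relation: positive
  - channel: CD28
    relation: positive
- name: cd8_tem_late
  tube: falcon
  parent: cd8_tem
  predicates:
  - channel: CD27
    relation: negative
  - channel: CD28
    relation: negative
- name: cd8_temra
  tube: falcon
  parent: cd8_t_cells
  predicates:
  - channel: CCR7
    relation: negative
  - channel: CD45RA
    relation: positive
- name: cd8_temra_early
  tube: falcon
  parent: cd8_temra
  predicates:
  - channel: CD27
    relation: positive
  - channel: CD28
    relation: positive
- name: cd8_temra_late
  tube: falcon
  parent: cd8_temra
  predicates:
  - channel: CD27
    relation: negative
  - channel: CD28
    relation: negative
- name: tregs
  tube: falcon
  parent: cd4_t_cells
  predicates:
  - channel: CD25
    relation: positive
  - channel: CD127
    relation: negative
- name: naive_tregs
  tube: falcon
  parent: tregs
  predicates:
  - channel: CD45RA
    relation: positive
- name: tfh
  tube: falcon
  parent: cd4_t_cells
  predicates:
  - channel: CXCR5
    relation: positive
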