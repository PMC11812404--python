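# Metabolite registry: polyamines and related biochemicals of the
# gut-microbiome polyamine pathway, with the Fmoc derivative quantified by
# LC-HRMS (fully derivatized for SPD/PUT, mono-Fmoc otherwise) or, for
# HILIC-measured species (SAM, MTA, acetylputrescine), the underivatized ion.
# rt windows (min) are nominal centres used by the synthetic mzML writer.
- name: spermidine
  formula: C7H19N3
  n_tags: 3
  reactive_amines: 3
  rt_window: [5.5, 6.1]
  polarity: positive
- name: putrescine
  formula: C4H12N2
  n_tags: 2
  reactive_amines: 2
  rt_window: [4.9, 5.5]
  polarity: positive
- name: ornithine
  formula: C5H12N2O2
  n_tags: 1
  reactive_amines: 2
  rt_window: [3.0, 3.6]
  polarity: positive
- name: citrulline
  formula: C6H13N3O3
  n_tags: 1
  reactive_amines: 2
  rt_window: [2.8, 3.4]
  polarity: positive
- name: arginine
  formula: C6H14N4O2
  n_tags: 1
  reactive_amines: 2
  rt_window: [2.6, 3.2]
  polarity: positive
- name: agmatine
  formula: C5H14N4
  n_tags: 1
  reactive_amines: 2
  rt_window: [3.4, 4.0]
  polarity: positive
- name: carbamoylputrescine
  formula: C5H13N3O
  n_tags: 1
  reactive_amines: 2
  rt_window: [3.8, 4.4]
  polarity: positive
- name: acetylputrescine
  formula: C6H14N2O
  n_tags: 0
  reactive_amines: 1
  rt_window: [7.2, 7.8]
  polarity: positive
- name: diacetylspermidine
  formula: C11H23N3O2
  n_tags: 1
  reactive_amines: 1
  rt_window: [4.4, 5.0]
  polarity: positive
- name: glutamate
  formula: C5H9NO4
  n_tags: 1
  reactive_amines: 1
  rt_window: [2.2, 2.8]
  polarity: positive
- name: sam
  formula: C15H22N6O5S
  n_tags: 0
  reactive_amines: 0
  rt_window: [8.0, 8.6]
  polarity: positive
- name: mta
  formula: C11H15N5O3S
  n_tags: 0
  reactive_amines: 0
  rt_window: [8.8, 9.4]
  polarity: positive
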