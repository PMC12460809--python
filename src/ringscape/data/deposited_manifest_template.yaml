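# Template manifest for the deposited NSF / sx20S / bin20S coordinate models.
#
# This is a TEMPLATE, not a verified mapping: download each entry from the
# PDB (e.g. https://files.rcsb.org/download/<ID>.cif), place the files under
# the paths below, and verify the D1 ring chain labels of each model before
# running (chains A-F below follow the common NSF hexamer deposition
# convention but MUST be checked against the files). Local-refinement
# subcomplex depositions (9OJJ, 9OK3, 9OM6, 9PFG) contain no NSF ring and
# are omitted. The published protomer ensemble used 132 D1 protomers from 22
# models; make the model roster for a given analysis explicit by deleting
# entries rather than guessing.
models:
  - {path: models/9OJ2.cif, id: 9OJ2, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OJR.cif, id: 9OJR, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OJU.cif, id: 9OJU, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OJZ.cif, id: 9OJZ, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OK5.cif, id: 9OK5, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OKC.cif, id: 9OKC, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OLJ.cif, id: 9OLJ, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OLO.cif, id: 9OLO, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9OMQ.cif, id: 9OMQ, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PAF.cif, id: 9PAF, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PAG.cif, id: 9PAG, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PB9.cif, id: 9PB9, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PBA.cif, id: 9PBA, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PBF.cif, id: 9PBF, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PBV.cif, id: 9PBV, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PC3.cif, id: 9PC3, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PCX.cif, id: 9PCX, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PCZ.cif, id: 9PCZ, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PD1.cif, id: 9PD1, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PD8.cif, id: 9PD8, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PDB.cif, id: 9PDB, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PDD.cif, id: 9PDD, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PF2.cif, id: 9PF2, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PFC.cif, id: 9PFC, condition: hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
  - {path: models/9PFF.cif, id: 9PFF, condition: non_hydrolyzing, chains: {A: A, B: B, C: C, D: D, E: E, F: F}}
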