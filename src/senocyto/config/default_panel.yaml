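# Full CyTOF antibody panel: metal tag, marker, channel category.
# Identity markers drive population clustering; senescence/sasp/dna_damage/
# anti_apoptosis/proliferation form the senescence statistics panel;
# instrument_* channels carry acquisition signals.
version: "1.0"
channels:
  - {marker: CD45, metal: 89Y, category: lineage}
  - {marker: CD146, metal: 141Pr, category: identity}
  - {marker: LeptinR, metal: 146Nd, category: identity}
  - {marker: Nestin, metal: 168Er, category: identity}
  - {marker: Sca-1, metal: 169Tm, category: identity}
  - {marker: CD24, metal: 142Nd, category: identity}
  - {marker: PDGFRa, metal: 148Nd, category: identity}
  - {marker: CXCL12, metal: 144Nd, category: identity}
  - {marker: OsteolectinR, metal: 156Gd, category: identity}
  - {marker: CD200, metal: 152Sm, category: identity}
  - {marker: CD29, metal: 158Gd, category: identity}
  - {marker: Runx2, metal: 147Sm, category: identity}
  - {marker: Osterix, metal: 151Eu, category: identity}
  - {marker: ALPL, metal: 154Sm, category: identity}
  - {marker: OCN, metal: 111Cd, category: identity}
  - {marker: Dmp1, metal: 143Nd, category: identity}
  - {marker: Podoplanin, metal: 174Yb, category: identity}
  - {marker: Sclerostin, metal: 166Er, category: identity}
  - {marker: PPARg, metal: 153Eu, category: identity}
  - {marker: Adiponectin, metal: 170Er, category: identity}
  - {marker: FLAG, metal: 164Dy, category: transgene}
  - {marker: MCP-1, metal: 149Sm, category: sasp}
  - {marker: TNFa, metal: 162Dy, category: sasp}
  - {marker: PAI-1, metal: 160Gd, category: sasp}
  - {marker: IL-6, metal: 167Er, category: sasp}
  - {marker: IL-1a, metal: 171Yb, category: sasp}
  - {marker: IL-1b, metal: 159Tb, category: sasp}
  - {marker: CXCL1, metal: 175Lu, category: sasp}
  - {marker: pNFkB, metal: 110Cd, category: sasp}
  - {marker: CENP-B, metal: 145Nd, category: senescence}
  - {marker: p21, metal: 176Yb, category: senescence}
  - {marker: p16, metal: 155Gd, category: senescence}
  - {marker: p53, metal: 116Cd, category: senescence}
  - {marker: yH2A-X, metal: 173Yb, category: dna_damage}
  - {marker: pATM, metal: 114Cd, category: dna_damage}
  - {marker: BCL-2, metal: 112Cd, category: anti_apoptosis}
  - {marker: Ki67, metal: 106Cd, category: proliferation}
  - {marker: DNA, metal: 191Ir, category: instrument_dna}
  - {marker: Viability, metal: 195Pt, category: instrument_viability}
  - {marker: Bead, metal: 140Ce, category: instrument_bead}
  - {marker: Event_length, metal: "", category: instrument_event_length}
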