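# Murine lung multispectral panel: 25 antibodies over 13 detector channels.
# Antibodies used in several tissue compartments of the lung
# (CD90, CD146, Ly6C, CD117, CD24) appear once each: the panel is one master
# stain and the 13-detector count is only meaningful within a single tube.
# CD64 and MerTK are deliberately coupled to the same fluorochrome and read
# as one combined macrophage readout.
entries:
  - {antigen: CD31,    fluorochrome: PE-Cy7,        dilution: 5000, target: "BECs, LECs"}
  - {antigen: CD90,    fluorochrome: PE,            dilution: 50,   target: "LECs, fibroblasts, lymphocytes"}
  - {antigen: CD146,   fluorochrome: AF488,         dilution: 100,  target: "BECs, VSMCs"}
  - {antigen: Ly6C,    fluorochrome: PerCP-Cy5.5,   dilution: 100,  target: "BECs, monocytes"}
  - {antigen: CD117,   fluorochrome: APC-eFluor780, dilution: 200,  target: "Epithelial cells, DCs, mast cells"}
  - {antigen: CD140,   fluorochrome: PE,            dilution: 50,   target: "Fibroblasts"}
  - {antigen: CD324,   fluorochrome: AF647,         dilution: 100,  target: "Epithelial cells"}
  - {antigen: CD326,   fluorochrome: BV711,         dilution: 100,  target: "Epithelial cells"}
  - {antigen: CD11b,   fluorochrome: BV605,         dilution: 200,  target: "Monocytes, eosinophils, neutrophils"}
  - {antigen: CD11c,   fluorochrome: BV711,         dilution: 50,   target: "AMs"}
  - {antigen: CD24,    fluorochrome: PE-CF594,      dilution: 333,  target: "cDCs, B cells"}
  - {antigen: CD44,    fluorochrome: AF700,         dilution: 50,   target: "AMs"}
  - {antigen: CD45,    fluorochrome: VioBlue,       dilution: 50,   target: "All leukocytes"}
  - {antigen: CD64,    fluorochrome: PE-Cy7,        dilution: 50,   target: "IMs", combined_group: macrophage}
  - {antigen: Ly6G,    fluorochrome: APC-Cy7,       dilution: 66,   target: "Neutrophils"}
  - {antigen: MerTK,   fluorochrome: PE-Cy7,        dilution: 50,   target: "IMs", combined_group: macrophage}
  - {antigen: MHCII,   fluorochrome: APC,           dilution: 200,  target: "cDCs, IMs"}
  - {antigen: SiglecF, fluorochrome: PE,            dilution: 50,   target: "Eosinophils"}
  - {antigen: CD3,     fluorochrome: APC-Cy7,       dilution: 50,   target: "T cells"}
  - {antigen: CD4,     fluorochrome: BV711,         dilution: 100,  target: "CD4+ T cells"}
  - {antigen: CD8a,    fluorochrome: BV650,         dilution: 200,  target: "CD8+ T cells"}
  - {antigen: GITR,    fluorochrome: FITC,          dilution: 100,  target: "Tregs"}
  - {antigen: NK1.1,   fluorochrome: BV510,         dilution: 100,  target: "NK cells"}
  - {antigen: SiglecH, fluorochrome: FITC,          dilution: 100,  target: "pDCs"}
  - {antigen: gdTCR,   fluorochrome: APC,           dilution: 33,   target: "gd T cells"}
channel_map:
  FITC: FITC_AF488
  AF488: FITC_AF488
  PE: PE
  PE-CF594: PE-CF594
  PerCP-Cy5.5: PerCP-Cy5.5
  PE-Cy7: PE-Cy7
  APC: APC_AF647
  AF647: APC_AF647
  AF700: AF700
  APC-Cy7: APC-Cy7_APC-eF780
  APC-eFluor780: APC-Cy7_APC-eF780
  VioBlue: VioBlue
  BV510: BV510
  BV605: BV605
  BV650: BV650
  BV711: BV711
viability_channel: 7AAD
scatter_params: [FSC-A, FSC-W, SSC-A]
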