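# Intracellular endpoint panel: 14 antibody/fluorochrome assignments (one
# viability dye) and the gating tree for the cytotoxic/regulatory populations
# reported at the study endpoint.
#
# Flagged ambiguities (kept out of the tree rather than guessed):
#   * TIM-3, PD1 and CTLA4 are acquired (inhibitory/exhaustion markers) but
#     their gate placement is not unambiguously documented in the source
#     material for any reported subset; they stay registry-only here.
#   * "Activated" NK status is operationalized as CD25+.
schema_version: 1
panel:
  name: intracellular
  scatter_channels: [FSC, SSC]
  markers:
    - {marker: Viability, channel: VioBlue,       role: viability}
    - {marker: CD3,       channel: VioGreen,      role: surface}
    - {marker: NK1.1,     channel: BV570,         role: surface}
    - {marker: CD25,      channel: BV605,         role: surface}
    - {marker: CD4,       channel: BV650,         role: surface}
    - {marker: GranzymeB, channel: FITC,          role: intracellular}
    - {marker: FOXP3,     channel: PE,            role: intracellular}
    - {marker: CD8,       channel: PE-Vio615,     role: surface}
    - {marker: TIM-3,     channel: PerCP-Cy5.5,   role: surface}
    - {marker: PD1,       channel: PerCP-Vio700,  role: surface}
    - {marker: CTLA4,     channel: PE-Vio770,     role: intracellular}
    - {marker: Perforin,  channel: APC,           role: intracellular}
    - {marker: CD44,      channel: APC-Cy5,       role: surface}
    - {marker: CCR5,      channel: APC-Cy7,       role: surface}
hierarchy:
  panel: intracellular
  leukocyte_node: viable_cells
  scatter_gate:
    FSC: [15000, 150000]
    SSC: [5000, 120000]
  root:
    name: intact_cells
    children:
      - name: viable_cells
        conditions:
          - {channel: Viability, relation: negative}
        children:
          - name: Tcells
            reported: true
            conditions:
              - {channel: CD3, relation: positive}
            children:
              - name: CD4_Tcells
                reported: true
                conditions:
                  - {channel: CD4, relation: positive}
                  - {channel: NK1.1, relation: negative}
                children:
                  - name: Treg
                    conditions:
                      - {channel: CD25, relation: positive}
                      - {channel: FOXP3, relation: positive}
                    children:
                      - name: CD4_Eff_Treg_CCR5
                        reported: true
                        conditions:
                          - {channel: CD44, relation: positive}
                          - {channel: CCR5, relation: positive}
              - name: CD8_Tcells
                reported: true
                conditions:
                  - {channel: CD8, relation: positive}
                  - {channel: NK1.1, relation: negative}
                children:
                  - name: Cytotoxic_CD8
                    reported: true
                    conditions:
                      - {channel: GranzymeB, relation: positive}
                      - {channel: Perforin, relation: positive}
              - name: NKT
                reported: true
                conditions:
                  - {channel: NK1.1, relation: positive}
                children:
                  - name: NKT_GzmB_pos_Perf_neg
                    reported: true
                    conditions:
                      - {channel: GranzymeB, relation: positive}
                      - {channel: Perforin, relation: negative}
          - name: NK_cells
            conditions:
              - {channel: CD3, relation: negative}
              - {channel: NK1.1, relation: positive}
            children:
              - name: NK_Perforin
                reported: true
                conditions:
                  - {channel: Perforin, relation: positive}
              - name: NK_act_Perf_pos_GzmB_neg
                reported: true
                conditions:
                  - {channel: CD25, relation: positive}
                  - {channel: Perforin, relation: positive}
                  - {channel: GranzymeB, relation: negative}
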