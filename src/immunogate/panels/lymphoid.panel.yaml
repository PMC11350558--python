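# Lymphoid peripheral-blood panel: 14 antibody/fluorochrome assignments and the
# gating tree resolving 26 reported lymphoid subset variables.
#
# T-helper subsets are resolved by chemokine-receptor phenotype within CD4+
# T cells (CXCR3 / CCR4 / CCR6), memory subsets by the CD44 x CD62L grid,
# regulatory T cells by CD25 and TNF-RII.  All gates are conjunctions of
# per-channel thresholds in asinh space.
schema_version: 1
panel:
  name: lymphoid
  scatter_channels: [FSC, SSC]
  markers:
    - {marker: CCR4,    channel: PE,           role: surface}
    - {marker: CCR6,    channel: BV605,        role: surface}
    - {marker: CD138,   channel: PE-Vio770,    role: surface}
    - {marker: CD19,    channel: BV570,        role: surface}
    - {marker: CD25,    channel: FITC,         role: surface}
    - {marker: CD3,     channel: VioBlue,      role: surface}
    - {marker: CD4,     channel: BV650,        role: surface}
    - {marker: CD44,    channel: APC-Cy5,      role: surface}
    - {marker: CD45,    channel: VioGreen,     role: surface}
    - {marker: CD62L,   channel: PerCP-Cy5.5,  role: surface}
    - {marker: CD8,     channel: PE-Vio615,    role: surface}
    - {marker: CXCR3,   channel: APC-Cy7,      role: surface}
    - {marker: NK1.1,   channel: APC,          role: surface}
    - {marker: TNF-RII, channel: PerCP-Vio700, role: surface}
hierarchy:
  panel: lymphoid
  leukocyte_node: Lymphocytes
  scatter_gate:
    FSC: [15000, 150000]
    SSC: [5000, 120000]
  root:
    name: intact_cells
    children:
      - name: Lymphocytes
        reported: true
        conditions:
          - {channel: CD45, relation: positive}
        children:
          - name: CD3_Tcells
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
                  - name: CD4_Naive
                    reported: true
                    conditions:
                      - {channel: CD44, relation: negative}
                      - {channel: CD62L, relation: positive}
                  - name: CD4_act_eff
                    reported: true
                    conditions:
                      - {channel: CD44, relation: negative}
                      - {channel: CD62L, relation: negative}
                  - name: CD4_CD44
                    reported: true
                    conditions:
                      - {channel: CD44, relation: positive}
                    children:
                      - name: CD4_Cmem
                        reported: true
                        conditions:
                          - {channel: CD62L, relation: positive}
                      - name: CD4_Emem
                        reported: true
                        conditions:
                          - {channel: CD62L, relation: negative}
                  - name: Th1
                    reported: true
                    conditions:
                      - {channel: CXCR3, relation: positive}
                      - {channel: CD25, relation: negative}
                    children:
                      - name: Th1_Eff
                        reported: true
                        conditions:
                          - {channel: CD62L, relation: negative}
                  - name: Th2
                    reported: true
                    conditions:
                      - {channel: CXCR3, relation: negative}
                      - {channel: CCR4, relation: positive}
                      - {channel: CCR6, relation: negative}
                      - {channel: CD25, relation: negative}
                    children:
                      - name: Th2_Eff
                        reported: true
                        conditions:
                          - {channel: CD62L, relation: negative}
                  - name: Th17
                    reported: true
                    conditions:
                      - {channel: CXCR3, relation: negative}
                      - {channel: CCR4, relation: positive}
                      - {channel: CCR6, relation: positive}
                      - {channel: CD25, relation: negative}
                    children:
                      - name: Th17_Eff
                        reported: true
                        conditions:
                          - {channel: CD62L, relation: negative}
                  - name: Th9
                    reported: true
                    conditions:
                      - {channel: CXCR3, relation: negative}
                      - {channel: CCR4, relation: negative}
                      - {channel: CCR6, relation: positive}
                      - {channel: CD25, relation: negative}
                  - name: CD4_Treg
                    reported: true
                    conditions:
                      - {channel: CD25, relation: positive}
                      - {channel: TNF-RII, relation: positive}
              - name: CD8_T_cells
                reported: true
                conditions:
                  - {channel: CD8, relation: positive}
                  - {channel: CD4, relation: negative}
                  - {channel: NK1.1, relation: negative}
                children:
                  - name: CD8_Naive
                    reported: true
                    conditions:
                      - {channel: CD44, relation: negative}
                      - {channel: CD62L, relation: positive}
                  - name: CD8_act_eff
                    reported: true
                    conditions:
                      - {channel: CD44, relation: negative}
                      - {channel: CD62L, relation: negative}
                  - name: CD8_CD44
                    reported: true
                    conditions:
                      - {channel: CD44, relation: positive}
                    children:
                      - name: CD8_Cmem
                        reported: true
                        conditions:
                          - {channel: CD62L, relation: positive}
                      - name: CD8_Emem
                        reported: true
                        conditions:
                          - {channel: CD62L, relation: negative}
              - name: NKT
                reported: true
                conditions:
                  - {channel: NK1.1, relation: positive}
          - name: NK
            reported: true
            conditions:
              - {channel: CD3, relation: negative}
              - {channel: NK1.1, relation: positive}
          - name: B_Lymphocytes
            reported: true
            conditions:
              - {channel: CD3, relation: negative}
              - {channel: NK1.1, relation: negative}
              - {channel: CD19, relation: positive}
            children:
              - name: Plasma_Cells
                reported: true
                conditions:
                  - {channel: CD138, relation: positive}
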