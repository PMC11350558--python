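# Myeloid peripheral-blood panel: 14 antibody/fluorochrome assignments and the
# gating tree resolving 16 reported myeloid subset variables.
#
# Notes for reviewers (immunologists welcome — this file is the single source
# of truth for the gate logic; corrections never require code changes):
#   * Gates are conjunctions of per-channel thresholds applied to
#     asinh-transformed intensities (rectangle gates), not free-hand polygons.
#   * CD80 and CD86 are both acquired on the APC detector as a co-stimulation
#     cocktail; they are listed as separate reagents with distinguishing
#     channel labels so the registry stays one-detector-per-row.
#   * Ly6C is gated at three levels (low / intermediate / high): monocyte
#     subsets split on Ly6C-high vs Ly6C-low, granulocytic MDSCs on Ly6C-low.
schema_version: 1
panel:
  name: myeloid
  scatter_channels: [FSC, SSC]
  markers:
    - {marker: B220,     channel: APC-Vio770-B220,  role: surface}
    - {marker: CCR2,     channel: PE-Vio770,        role: surface}
    - {marker: CD11b,    channel: PerCP-Vio700,     role: surface}
    - {marker: CD11c,    channel: APC-Cy7,          role: surface}
    - {marker: CD172a,   channel: VioBlue,          role: surface}
    - {marker: CD45,     channel: VioGreen,         role: surface}
    - {marker: CD49b,    channel: PE-Vio615,        role: surface}
    - {marker: Ly6C,     channel: PerCP-Cy5.5,      role: surface}
    - {marker: CD80,     channel: APC (CD80),       role: surface}
    - {marker: CD86,     channel: APC (CD86),       role: surface}
    - {marker: F4_80,    channel: FITC,             role: surface}
    - {marker: Ly6G,     channel: BV605,            role: surface}
    - {marker: MHC-II,   channel: BV650,            role: surface}
    - {marker: Siglec-F, channel: PE,               role: surface}
hierarchy:
  panel: myeloid
  leukocyte_node: CD45_Leukocytes
  scatter_gate:
    FSC: [15000, 150000]
    SSC: [5000, 120000]
  root:
    name: intact_cells
    children:
      - name: CD45_Leukocytes
        reported: true
        conditions:
          - {channel: CD45, relation: positive}
        children:
          - name: CD45_Myeloid
            reported: true
            conditions:
              - {channel: CD11b, relation: positive}
            children:
              - name: Granulocytes
                reported: true
                conditions:
                  - {channel: Ly6G, relation: positive}
                children:
                  - name: Neutrophils
                    reported: true
                    conditions:
                      - {channel: Siglec-F, relation: negative}
                  - name: Eosinophils
                    reported: true
                    conditions:
                      - {channel: Siglec-F, relation: positive}
                  - name: PMN_MDSCs
                    reported: true
                    conditions:
                      - {channel: Siglec-F, relation: negative}
                      - {channel: Ly6C, relation: low}
              - name: Total_Monocytes
                reported: true
                conditions:
                  - {channel: Ly6G, relation: negative}
                  - {channel: F4_80, relation: positive}
                children:
                  - name: Classical_Monocytes
                    reported: true
                    conditions:
                      - {channel: Ly6C, relation: high}
                      - {channel: CCR2, relation: positive}
                  - name: Non_classical_monocytes
                    reported: true
                    conditions:
                      - {channel: Ly6C, relation: low}
                  - name: M_MDSCs
                    reported: true
                    conditions:
                      - {channel: Ly6C, relation: high}
                      - {channel: CCR2, relation: negative}
              - name: Basophils
                reported: true
                conditions:
                  - {channel: Ly6G, relation: negative}
                  - {channel: F4_80, relation: negative}
                  - {channel: CD49b, relation: positive}
          - name: CD172a_Myeloids
            reported: true
            conditions:
              - {channel: CD172a, relation: positive}
          - name: Dendritic_cells
            conditions:
              - {channel: CD11b, relation: negative}
              - {channel: CD11c, relation: positive}
            children:
              - name: p_DC
                reported: true
                conditions:
                  - {channel: B220, relation: positive}
                children:
                  - name: Mature_pDC
                    reported: true
                    conditions:
                      - {channel: MHC-II, relation: positive}
              - name: cDC1
                reported: true
                conditions:
                  - {channel: B220, relation: negative}
                  - {channel: MHC-II, relation: positive}
                children:
                  - name: mature_cDC1
                    reported: true
                    conditions:
                      - {channel: CD80, relation: positive}
                      - {channel: CD86, relation: positive}
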