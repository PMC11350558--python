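panel,variable,eta_intra_pct,eta_inter_pct,mdc_cells,mdc_pct
myeloid,CD45_Leukocytes,35.15,23.24,363.44,11.68
myeloid,CD45_Myeloid,54.53,12.70,148.52,17.41
myeloid,CD172a_Myeloids,42.25,24.21,103.11,14.71
myeloid,Granulocytes,27.37,32.33,80.04,14.07
myeloid,Basophils,33.86,19.03,6.043,19.04
myeloid,Neutrophils,41.48,23.15,39.93,18.51
myeloid,Eosinophils,18.17,48.83,19.40,19.47
myeloid,Classical_Monocytes,56.67,17.54,1.06,32.65
myeloid,Non_classical_monocytes,41.12,34.31,2.89,27.97
myeloid,Total_Monocytes,28.68,45.25,36.48,21.90
myeloid,p_DC,64.68,4.88,0.28,38.09
myeloid,Mature_pDC,51.10,2.94,0.17,38.34
myeloid,cDC1,16.86,33.11,0.25,29.39
myeloid,mature_cDC1,16.88,16.88,0.07,30.84
myeloid,PMN_MDSCs,19.04,13.77,3.59,19.48
myeloid,M_MDSCs,20.03,14.22,14.68,16.23
lymphoid,Lymphocytes,37.41,34.31,347.58,16.28
lymphoid,CD3_Tcells,31.01,37.26,93.22,18.66
lymphoid,CD4_Tcells,34.89,34.37,40.92,17.72
lymphoid,CD4_Naive,49.38,5.53,37.00,49.58
lymphoid,CD4_act_eff,48.64,14.63,34.51,27.13
lymphoid,CD4_Cmem,36.90,18.04,1.44,33.93
lymphoid,CD4_Emem,60.87,18.62,4.93,19.85
lymphoid,CD4_CD44,53.81,13.46,3.90,15.93
lymphoid,Th1,57.32,11.61,0.25,32.26
lymphoid,Th1_Eff,32.73,29.35,0.03,37.22
lymphoid,Th2,65.73,11.52,0.23,54.015
lymphoid,Th2_Eff,21.74,32.34,0.05,44.73
lymphoid,Th9,65.74,12.99,2.44,27.66
lymphoid,Th17,77.49,3.97,0.33,46.06
lymphoid,Th17_Eff,49.79,14.30,0.07,57.08
lymphoid,CD4_Treg,52.32,17.97,0.18,32.77
lymphoid,CD8_T_cells,23.99,48.13,38.82,20.14
lymphoid,CD8_Naive,45.53,10.11,31.85,37.40
lymphoid,CD8_act_eff,43.55,17.96,28.65,37.44
lymphoid,CD8_Cmem,16.57,54.62,5.50,25.24
lymphoid,CD8_Emem,15.42,32.61,2.85,30.89
lymphoid,CD8_CD44,29.49,33.52,0.50,29.56
lymphoid,B_Lymphocytes,20.16,45.08,291.87,20.50
lymphoid,Plasma_Cells,9.80,76.16,10.11,56.15
lymphoid,NKT,41.20,14.93,14.13,26.59
lymphoid,NK,31.41,37.10,13.38,19.05
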