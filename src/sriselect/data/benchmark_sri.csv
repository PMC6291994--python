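protein,pdb_id,role,model,sri_1,sri_2,sri_3,sri_4,sri_5,sri_6,sri_7,sri_8
albumin,1ao6,predicted,,15.10,16.08,22.41,19.45,18.14,9.48,15.04,7.80
albumin,1ao6,calculated_reference,,8.22,12.68,12.31,7.70,9.91,9.27,10.09,11.62
albumin,1ao6,calculated_model,1,9.43,11.42,7.45,12.94,13.06,9.81,7.84,9.92
albumin,1ao6,calculated_model,2,14.43,11.44,7.11,12.88,11.72,11.68,9.20,9.21
albumin,1ao6,calculated_model,3,8.80,11.27,7.18,13.46,13.82,10.34,9.35,8.29
albumin,1ao6,calculated_model,4,11.03,15.31,13.86,8.48,14.31,8.76,7.41,11.17
albumin,1ao6,calculated_model,5,9.40,11.46,8.55,13.69,13.45,9.64,8.41,9.70
cytochrome_c,1new,predicted,,5.38,5.83,4.70,2.55,5.11,4.19,3.40,3.70
cytochrome_c,1new,calculated_reference,,3.45,5.45,4.24,2.02,3.35,2.88,3.47,3.74
cytochrome_c,1new,calculated_model,1,4.93,3.77,4.33,1.07,3.11,3.27,3.60,4.07
cytochrome_c,1new,calculated_model,2,4.01,0.00,1.83,5.01,3.29,3.40,3.99,3.42
cytochrome_c,1new,calculated_model,3,4.41,7.79,1.75,3.77,2.90,3.32,2.13,3.95
cytochrome_c,1new,calculated_model,4,3.63,3.58,4.10,1.13,3.66,3.37,4.71,3.97
cytochrome_c,1new,calculated_model,5,4.88,4.28,3.37,3.75,2.56,3.07,3.60,4.38
ferritin,1ro3,predicted,,4.12,5.23,4.99,3.08,6.33,3.14,3.66,3.23
ferritin,1ro3,calculated_reference,,0.02,3.20,1.47,0.11,2.14,1.54,2.56,1.77
ferritin,1ro3,calculated_model,1,1.73,3.01,1.38,5.41,3.58,0.61,4.92,1.74
ferritin,1ro3,calculated_model,2,6.31,3.74,5.98,0.90,1.54,4.50,0.00,4.84
ferritin,1ro3,calculated_model,3,2.78,2.66,3.12,4.61,2.77,2.82,3.35,1.37
ferritin,1ro3,calculated_model,4,6.43,0.00,7.66,3.60,0.91,3.39,1.42,2.90
ferritin,1ro3,calculated_model,5,4.15,2.26,1.90,5.25,3.62,1.79,3.25,0.14
lysozyme,2vb1,predicted,,3.51,4.29,5.36,4.05,2.84,4.06,4.84,3.93
lysozyme,2vb1,calculated_reference,,4.19,3.32,5.05,5.32,4.23,3.05,2.92,3.83
lysozyme,2vb1,calculated_model,1,4.81,4.51,2.77,3.07,4.24,3.12,3.74,3.83
lysozyme,2vb1,calculated_model,2,4.06,4.45,2.97,3.30,4.28,2.93,3.63,3.67
lysozyme,2vb1,calculated_model,3,3.86,4.47,2.79,3.26,4.51,3.06,3.89,3.84
lysozyme,2vb1,calculated_model,4,4.23,4.49,3.84,3.16,4.33,3.01,3.65,3.97
lysozyme,2vb1,calculated_model,5,5.81,4.32,2.93,3.03,4.55,2.42,3.76,4.00
insulin,2h8b,predicted,,4.59,5.37,5.30,6.23,3.67,4.19,3.51,5.39
insulin,2h8b,calculated_reference,,1.66,6.09,4.07,3.96,2.54,3.20,1.92,4.20
insulin,2h8b,calculated_model,1,2.07,7.54,5.77,2.12,9.05,2.96,3.96,5.67
insulin,2h8b,calculated_model,2,5.53,4.82,3.14,1.55,8.68,5.22,2.71,1.91
insulin,2h8b,calculated_model,3,5.75,2.87,2.42,5.13,6.77,3.96,2.11,4.96
insulin,2h8b,calculated_model,4,7.57,3.27,6.87,2.72,5.49,4.43,1.76,5.99
insulin,2h8b,calculated_model,5,6.66,3.71,4.77,2.86,1.76,3.98,3.04,5.26
hemoglobin,1a3n,predicted,,5.95,8.82,8.59,10.99,9.28,4.96,8.71,8.36
hemoglobin,1a3n,calculated_reference,,7.80,8.31,8.69,10.99,8.73,6.31,9.10,6.73
hemoglobin,1a3n,calculated_model,1,8.85,9.44,9.54,10.29,7.77,9.74,7.95,11.05
hemoglobin,1a3n,calculated_model,2,9.12,6.62,9.65,8.43,4.89,7.73,8.46,9.05
hemoglobin,1a3n,calculated_model,3,9.00,5.55,9.52,7.94,4.98,7.69,8.47,8.94
hemoglobin,1a3n,calculated_model,4,7.09,8.35,8.26,8.80,8.40,6.47,9.16,6.49
hemoglobin,1a3n,calculated_model,5,9.12,6.62,9.65,8.43,4.89,7.73,8.46,9.05
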