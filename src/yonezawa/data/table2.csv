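study,source_table,tissue,endpoint,d1_gy,d2_gy,dt_h,t_h,n2_events,n2_denom,n12_events,n12_denom,delta,footnote
shadley_wolff,II,lymphocytes,chromatid_breaks,0.01,1.5,16,22,83,200,60,200,0.277,b
shadley_wolff,II,lymphocytes,chromatid_breaks,0.05,1.5,16,22,83,200,58,200,0.301,b
shadley_wolff,II,lymphocytes,chromatid_breaks,0.1,1.5,16,22,83,200,66,200,0.205,b
shadley_wolff,II,lymphocytes,chromatid_breaks,0.2,1.5,16,22,83,200,83,200,0.000,b
shadley_wolff,II,lymphocytes,chromatid_breaks,0.3,1.5,16,22,83,200,99,200,-0.193,b;d
shadley_wolff,II,lymphocytes,chromatid_breaks,0.4,1.5,16,22,83,200,103,200,-0.241,b;d
shadley_wolff,II,lymphocytes,chromatid_breaks,0.5,1.5,16,22,83,200,126,200,-0.518,b;d
shadley_etal,I,lymphocytes,chromatid_breaks,0.01,1.5,44,50,101,300,78,300,0.228,b
shadley_etal,I,lymphocytes,chromatid_breaks,0.01,1.5,40,46,101,300,73,300,0.277,b
shadley_etal,I,lymphocytes,chromatid_breaks,0.01,1.5,36,42,101,300,68,300,0.327,b
shadley_etal,I,lymphocytes,chromatid_breaks,0.01,1.5,34,40,101,300,73,300,0.277,b
shadley_etal,II,lymphocytes,chromatid_breaks,0.01,1.5,34,40,68,200,48,200,0.294,b
shadley_etal,II,lymphocytes,chromatid_breaks,0.01,1.5,32,38,68,200,51,200,0.250,b
shadley_etal,II,lymphocytes,chromatid_breaks,0.01,1.5,30,36,68,200,49,200,0.279,b
shadley_etal,II,lymphocytes,chromatid_breaks,0.01,1.5,28,34,68,200,47,200,0.309,b
shadley_etal,II,lymphocytes,chromatid_breaks,0.01,1.5,10,16,68,200,42,200,0.382,b
shadley_etal,III,lymphocytes,chromatid_breaks,0.01,1.5,14,20,68,200,40,200,0.412,b
shadley_etal,III,lymphocytes,chromatid_breaks,0.01,1.5,20,26,76,200,43,200,0.434,b
shadley_etal,III,lymphocytes,chromatid_breaks,0.01,1.5,38,44,71,200,36,200,0.493,b
shadley_etal,IV,lymphocytes,chromatid_breaks,0.01,1.5,18,24,84,200,55,200,0.345,b
shadley_etal,IV,lymphocytes,chromatid_breaks,0.01,1.5,36,42,92,200,55,200,0.402,b
shadley_etal,IV,lymphocytes,chromatid_breaks,0.01,1.5,60,66,88,200,83,200,0.057,b
shadley_etal,IV,lymphocytes,chromatid_breaks,0.01,1.5,84,90,93,200,88,200,0.054,b
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,2,6,30,95,100,48,100,0.495,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,4,6,30,188,100,143,100,0.239,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,2,6,30,90,100,74,100,0.178,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,4,6,30,240,100,166,100,0.308,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,2,6,30,69,100,55,100,0.203,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,4,6,30,118,100,65,100,0.449,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,2,6,30,106,100,87,100,0.179,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,4,6,30,218,100,176,100,0.193,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,2,6,30,58,100,51,100,0.121,c
shadley_dai,I,lymphocytes,chromosome_aberrations,0.05,4,6,30,192,100,147,100,0.234,c
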