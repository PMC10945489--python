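name,d_OH,phi_HOH,sigma_O,epsilon_O,q_H,year,extra_h_site
H2ODC,0.9580,109.47,3.184,0.14173,0.45495,2012,0
OPC3,0.9789,109.47,3.17427,0.16341,0.4476,2016,0
SPC,1.0,109.47,3.16557,0.1554,0.41,1981,0
SPC/E,1.0,109.47,3.16557,0.1554,0.4238,1987,0
SPC/eps,1.0,109.45,3.1785,0.1687,0.4245,2015,0
SPC/L,1.1,104.5,3.1487,0.16049,0.34425,2002,0
sTIP3P,0.9572,104.52,3.1507,0.1521,0.417,1998,1
TIP3P,0.9572,104.52,3.1507,0.1521,0.417,1981,0
TIP3P-EW,0.9572,104.52,3.188,0.102,0.415,2004,0
TIP3P-FB,1.0118,108.15,3.178,0.15583,0.424,2014,0
TIP3P-ST,1.023,108.11,3.19257,0.14386,0.42556,2019,0
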