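name,T_C,sd_T_C,rho_C,sd_rho_C,T_MD,sd_T_MD,rho_MD,sd_rho_MD,T_evap,sd_T_evap,source
H2ODC,608.6,2.0,289.1,2.9,254.4,1.1,1008.3,0.3,581.3,0.7,simulation
OPC3,629.1,2.1,299.0,2.1,253.9,1.1,1006.8,0.2,593.7,1.2,simulation
SPC,552.3,0.8,251.5,2.5,225.0,0.9,1009.5,0.3,531.5,1.5,simulation
SPC/E,599.1,1.3,287.2,1.8,249.8,0.5,1013.1,0.3,573.5,1.4,simulation
SPC/eps,648.3,1.1,319.9,1.9,270.4,1.0,1001.2,0.2,620.5,1.3,simulation
SPC/L,558.3,1.1,256.2,2.6,220.7,1.4,1037.9,0.2,535.7,1.7,simulation
sTIP3P,544.4,1.4,235.5,2.6,202.0,0.8,1042.5,0.7,526.5,1.7,simulation
TIP3P,541.6,2.5,231.6,3.2,199.1,2.0,1039.2,0.6,524.1,1.0,simulation
TIP3P-EW,539.1,0.9,230.8,4.1,222.2,1.2,1035.5,0.4,520.1,1.6,simulation
TIP3P-FB,626.8,1.2,297.6,1.2,258.5,1.5,1004.2,0.2,592.9,1.9,simulation
TIP3P-ST,651.7,2.6,312.9,1.2,277.8,2.2,1000.2,0.2,609.5,1.1,simulation
Exp,647.1,,322,,276.2,,999.1,,,,experiment
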