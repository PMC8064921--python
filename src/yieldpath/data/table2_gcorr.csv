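trait,Ei,HI,GY,RUE,AGR40,R8,R1,R5,RL,SFL,LAI,K,A,iWUE
Ei,0.65,,,,,,,,,,,,,
HI,0.07,0.68,,,,,,,,,,,,
GY,0.11,0.62,0.82,,,,,,,,,,,
RUE,-0.35,-0.14,0.20,0.36,,,,,,,,,,
AGR40,0.94,0.11,0.12,-0.27,0.71,,,,,,,,,
R8,-0.41,0.48,0.49,0.16,-0.33,0.69,,,,,,,,
R1,0.12,-0.32,-0.61,-0.35,0.05,-0.26,0.78,,,,,,,
R5,-0.08,-0.55,-0.41,0.13,-0.05,0.17,0.55,0.71,,,,,,
RL,-0.28,0.50,0.71,0.31,-0.19,0.73,-0.85,-0.29,0.84,,,,,
SFL,-0.47,0.30,0.29,0.07,-0.43,0.69,-0.18,0.15,0.51,0.61,,,,
LAI,0.23,-0.10,0.30,-0.09,0.30,0.26,-0.02,0.30,0.16,-0.27,0.56,,,
K,0.67,-0.04,-0.05,-0.33,0.64,-0.29,0.02,-0.05,-0.16,-0.57,0.37,0.43,,
A,-0.03,0.72,0.43,-0.12,-0.08,0.09,-0.27,-0.63,0.24,0.06,-0.18,-0.31,0.20,
iWUE,0.02,-0.18,-0.02,0.25,0.11,-0.36,-0.23,-0.43,-0.05,-0.30,-0.14,-0.19,0.12,0.20
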