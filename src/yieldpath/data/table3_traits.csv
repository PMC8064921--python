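trait,env,mean,min,max
Ei,ACRE_2017,56.3,50.7,59.4
Ei,ACRE_2018,52.8,47.2,57.9
Ei,RMN_2018,44.5,36.7,50.2
RUE,ACRE_2017,1.0,0.6,1.2
RUE,ACRE_2018,1.2,0.7,1.5
RUE,RMN_2018,1.3,0.8,1.5
HI,ACRE_2017,0.4,0.3,0.5
HI,ACRE_2018,0.4,0.2,0.5
HI,RMN_2018,0.4,0.3,0.5
GY,ACRE_2017,3178.2,1587.4,4768.1
GY,ACRE_2018,3793.2,2230.2,5159.8
GY,RMN_2018,3886.1,2504.7,5341.7
AGR40,ACRE_2017,1.2,0.9,1.4
AGR40,ACRE_2018,0.9,0.7,1.1
AGR40,RMN_2018,0.6,0.3,0.9
R8,ACRE_2017,114.6,108.8,121.0
R8,ACRE_2018,121.6,115.2,129.2
R8,RMN_2018,124.9,117.9,132.2
R1,ACRE_2017,39.1,33.9,46.0
R1,ACRE_2018,39.4,33.8,46.3
R1,RMN_2018,41.7,36.2,47.8
R5,ACRE_2017,67.5,65.8,69.8
R5,ACRE_2018,74.2,72.4,76.5
R5,RMN_2018,77.3,75.7,79.8
RL,ACRE_2017,75.5,65.0,85.1
RL,ACRE_2018,82.1,70.2,91.5
RL,RMN_2018,83.0,72.0,91.9
SFL,ACRE_2017,42.3,35.7,47.1
SFL,ACRE_2018,39.1,33.0,43.0
SFL,RMN_2018,39.9,34.0,44.1
LAI,ACRE_2017,5.3,2.7,7.6
LAI,ACRE_2018,4.0,1.0,7.3
LAI,RMN_2018,5.7,3.3,8.1
K,ACRE_2017,0.6,0.3,0.8
K,ACRE_2018,0.4,0.3,0.7
K,RMN_2018,0.4,0.2,0.6
A,ACRE_2017,27.0,23.0,30.6
A,ACRE_2018,27.3,22.3,31.8
A,RMN_2018,26.6,21.3,30.4
iWUE,ACRE_2017,20.2,0.6,54.4
iWUE,ACRE_2018,17.1,0.6,37.3
iWUE,RMN_2018,22.7,2.0,48.2
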