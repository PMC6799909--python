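measurement,class,group,mean,sd
V1T1,lengths,mediolateral,13.2,0.59
T1T2,lengths,mediolateral,10.0,0.93
V2T3,lengths,mediolateral,12.6,0.82
T3T4,lengths,mediolateral,18.2,0.69
V3T5,lengths,mediolateral,14.0,0.45
T5T6,lengths,mediolateral,12.0,0.65
V4T7,lengths,mediolateral,12.4,0.71
T7T8,lengths,mediolateral,10.7,0.42
T1T3,lengths,anteroposterior,4.4,0.60
T3T5,lengths,anteroposterior,18.3,0.55
T5T7,lengths,anteroposterior,11.5,0.39
T2T4,lengths,anteroposterior,9.6,0.93
T4T6,lengths,anteroposterior,13.3,0.86
T6T8,lengths,anteroposterior,12.0,0.72
V1V2T3T1,areas,array,71.2,1.81
T1T2T3T4,areas,array,61.2,5.56
V2V3T5T3,areas,array,168.6,5.74
T3T5T6T4,areas,array,215.5,19.64
V3V4T7T5,areas,array,126.0,4.17
T5T7T8T6,areas,array,129.7,4.88
Extension,angles,orientation,16,2.1
External rotation,angles,orientation,14,0.9
Abduction,angles,orientation,22,3.3
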