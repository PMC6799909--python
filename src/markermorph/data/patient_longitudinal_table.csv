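measurement,class,group,week_0,week_3,week_12,week_26
V1T1,lengths,mediolateral,11.0,16.3,23.3,29.4
V2T3,lengths,mediolateral,17.5,20.9,32.7,40.8
V3T5,lengths,mediolateral,23.9,26.7,36.3,41.5
V4T7,lengths,mediolateral,21.5,23.0,33.6,38.5
T1T3,lengths,anteroposterior,7.5,9.5,12.2,14.1
T3T5,lengths,anteroposterior,12.4,13.2,12.7,11.4
T5T7,lengths,anteroposterior,9.0,11.1,14.6,12.9
V1V2T3T1,areas,array,119.9,181.2,288.9,384.2
V2V3T5T3,areas,array,204.2,250.6,363.6,411.6
V3V4T7T5,areas,array,205.7,248.0,389.0,413.7
Extension,angles,orientation,2.3,4.6,2.0,4.0
External rotation,angles,orientation,28.4,56.4,59.1,56.9
Abduction,angles,orientation,17.2,9.0,5.2,0.3
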