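sex,age_months,median_cm,sd_cm
male,6,67.6,2.2
male,7,69.07,2.3
male,8,70.53,2.4
male,9,72.0,2.5
male,10,73.23,2.567
male,11,74.47,2.633
male,12,75.7,2.7
male,13,76.8,2.75
male,14,77.9,2.8
male,15,79.0,2.85
male,16,80.1,2.9
male,17,81.2,2.95
male,18,82.3,3.0
male,19,83.1,3.033
male,20,83.9,3.067
male,21,84.7,3.1
male,22,85.5,3.133
male,23,86.3,3.167
male,24,87.1,3.2
male,25,87.9,3.25
male,26,88.7,3.3
male,27,89.5,3.35
male,28,90.3,3.4
male,29,91.1,3.45
male,30,91.9,3.5
male,31,92.6,3.55
male,32,93.3,3.6
male,33,94.0,3.65
male,34,94.7,3.7
male,35,95.4,3.75
male,36,96.1,3.8
female,6,65.7,2.3
female,7,67.17,2.4
female,8,68.63,2.5
female,9,70.1,2.6
female,10,71.4,2.667
female,11,72.7,2.733
female,12,74.0,2.8
female,13,75.12,2.85
female,14,76.23,2.9
female,15,77.35,2.95
female,16,78.47,3.0
female,17,79.58,3.05
female,18,80.7,3.1
female,19,81.53,3.133
female,20,82.37,3.167
female,21,83.2,3.2
female,22,84.03,3.233
female,23,84.87,3.267
female,24,85.7,3.3
female,25,86.53,3.35
female,26,87.37,3.4
female,27,88.2,3.45
female,28,89.03,3.5
female,29,89.87,3.55
female,30,90.7,3.6
female,31,91.42,3.65
female,32,92.13,3.7
female,33,92.85,3.75
female,34,93.57,3.8
female,35,94.28,3.85
female,36,95.0,3.9
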