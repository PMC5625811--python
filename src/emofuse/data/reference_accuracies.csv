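subject,face,eeg,sum_fusion,production_fusion
1,92.5,67.5,92.5,87.5
2,57.5,70.0,82.5,87.5
3,50.0,72.5,87.5,87.5
4,62.5,75.0,92.5,87.5
5,60.0,60.0,75.0,75.0
6,87.5,75.0,95.0,92.5
7,72.5,72.5,72.5,80.0
8,70.0,70.0,80.0,87.5
9,92.5,60.0,75.0,80.0
10,85.0,62.5,72.5,80.0
11,67.5,72.5,80.0,80.0
12,80.0,75.0,85.0,85.0
13,92.5,57.5,92.5,87.5
14,72.5,55.0,77.5,80.0
15,70.0,52.5,75.0,77.5
16,92.5,62.5,77.5,77.5
17,77.5,57.5,90.0,87.5
18,92.5,80.0,92.5,85.0
19,50.0,62.5,60.0,75.0
20,62.5,77.5,70.0,75.0
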