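model_id,side,calyx,group_index,theta_x,theta_y,outcome
1,right,upper,1,8,46,passed
1,right,upper,2,53,0,passed
1,right,middle,1,15,47,passed
1,right,middle,2,40,0,passed
1,right,lower,1,-63,60,passed
1,right,lower,2,43,0,passed
2,right,upper,1,54,0,passed
2,right,middle,1,58,60,passed
2,right,middle,2,35,0,passed
2,right,lower,1,-56,60,passed
2,right,lower,2,-38,60,passed
2,right,lower,3,68,0,passed
3,right,upper,1,45,60,passed
3,right,middle,1,4,60,passed
3,right,middle,2,90,0,passed
3,right,lower,1,-67,60,passed
3,right,lower,2,45,60,passed
4,right,upper,1,90,0,failed
4,right,upper,2,53,60,failed
4,right,middle,1,38,60,passed
4,right,middle,2,87,60,passed
4,right,lower,1,-34,60,passed
4,right,lower,2,48,60,passed
5,right,upper,1,11,20,passed
5,right,upper,2,73,60,passed
5,right,middle,1,44,60,passed
5,right,middle,2,-13,57,passed
5,right,lower,1,-90,0,passed
5,right,lower,2,-14,60,passed
6,right,upper,1,16,22,passed
6,right,upper,2,53,60,passed
6,right,middle,1,14,60,passed
6,right,lower,1,-40,60,passed
6,right,lower,2,23,0,passed
7,left,upper,1,11,22,passed
7,left,upper,2,35,52,passed
7,left,middle,1,24,60,passed
7,left,lower,1,-88,0,passed_via_other_calyx
7,left,lower,2,90,60,passed_via_other_calyx
8,left,upper,1,25,60,passed
8,left,upper,2,23,16,passed
8,left,middle,1,-1,18,passed
8,left,middle,2,47,60,passed
8,left,lower,1,-45,15,passed
8,left,lower,2,67,50,passed
9,left,upper,1,15,47,passed
9,left,upper,2,40,0,passed
9,left,middle,1,-31,15,passed
9,left,middle,2,23,33,passed
9,left,lower,1,-59,33,passed
9,left,lower,2,41,24,passed
10,left,upper,1,-26,18,passed
10,left,upper,2,66,33,passed
10,left,middle,1,24,36,passed
10,left,lower,1,-62,17,passed
10,left,lower,2,44,21,passed
11,left,upper,1,45,40,passed
11,left,upper,2,23,5,passed
11,left,middle,1,32,11,passed
11,left,lower,1,-44,0,passed
11,left,lower,2,20,57,passed
12,left,upper,1,85,0,failed
12,left,upper,2,18,19,failed
12,left,middle,1,-31,37,passed
12,left,middle,2,28,35,passed
12,left,lower,1,-31,37,passed
12,left,lower,2,28,35,passed
13,left,upper,1,-4,0,passed
13,left,upper,2,45,0,passed
13,left,upper,3,30,60,passed
13,left,middle,1,17,17,passed
13,left,middle,2,30,60,passed
13,left,lower,1,-58,36,passed
13,left,lower,2,60,60,passed
14,left,upper,1,85,0,failed
14,left,upper,2,18,19,failed
14,left,middle,1,-25,60,passed
14,left,middle,2,0,60,passed
14,left,lower,1,-70,0,failed
14,left,lower,2,-5,60,failed
15,left,upper,1,39,22,failed
15,left,upper,2,38,27,failed
15,left,middle,1,10,40,passed
15,left,middle,2,60,48,passed
15,left,lower,1,-45,0,passed
15,left,lower,2,-51,60,passed
15,left,lower,3,67,60,passed
16,left,upper,1,24,22,passed
16,left,upper,2,38,27,passed
16,left,middle,1,-5,11,passed
16,left,middle,2,53,23,passed
16,left,lower,1,-45,56,passed
16,left,lower,2,90,0,passed
17,left,upper,1,66,30,failed
17,left,upper,2,5,40,failed
17,left,middle,1,21,48,passed
17,left,middle,2,90,0,passed
17,left,lower,1,-33,60,passed
17,left,lower,2,-27,60,passed
17,left,lower,3,73,0,passed
18,left,upper,1,38,35,passed
18,left,middle,1,-3,58,passed
18,left,middle,2,60,48,passed
18,left,lower,1,-90,0,passed_via_other_calyx
18,left,lower,2,50,55,passed_via_other_calyx
19,left,upper,1,67,44,failed
19,left,upper,2,-22,36,failed
19,left,upper,3,55,23,failed
19,left,middle,1,2,23,passed
19,left,middle,2,57,51,passed
19,left,lower,1,-39,0,passed
19,left,lower,2,56,60,passed
20,left,upper,1,2,0,passed
20,left,upper,2,51,48,passed
20,left,middle,1,16,38,passed
20,left,middle,2,64,60,passed
20,left,lower,1,-58,60,passed
20,left,lower,2,31,36,passed
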