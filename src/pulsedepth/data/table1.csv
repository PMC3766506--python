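subject,bmi,move_existing,move_proposed,cfs_existing,cfs_proposed,label_existing,label_proposed,newcfs_existing,newcfs_proposed
1,21.14,2.85,2.64,4.384492,3.385465,Floating,Floating,0.594,8.9492
2,21.56,5.91,6.23,5.139147,5.059429,Sinking,Sinking,7.4701,1.752
3,20.89,3.42,2.97,5.031552,6.724444,Sinking,Sinking,-3.896,-9.181
4,26.92,2.95,3.26,6.527585,3.335057,Sinking,Floating,-5.3811,1.946
5,27.77,3.43,4.04,5.087282,2.153485,Sinking,Floating,-3.1561,1.002
6,23.51,2.39,1.87,7.011686,6.520645,Sinking,Sinking,-14.059,-7.031
7,18.73,4.99,5.06,5.068592,6.613833,Sinking,Sinking,-3.7858,-6.58355
8,30.24,2.89,4.04,7.038385,2.393842,Sinking,Floating,-3.5957,5.1531
9,23.67,4.79,4.82,2.851511,2.613861,Floating,Floating,5.78025,3.7117
10,23.29,2.72,5.85,5.061054,7.596154,Sinking,Sinking,-5.8969,-15.498
11,20.42,2.97,4.11,2.382716,4.474097,Floating,Floating,6.0137,3.92475
12,20.95,4.22,5.46,4.998414,4.072165,Floating,Floating,-1.0088,-2.8427
13,19.13,2.36,3.8,3.193309,4.607309,Floating,Floating,8.77415,0.74365
14,22.98,4.5,5.53,4.331481,2.130134,Floating,Floating,12.6802,9.3022
15,26.77,3.3,4.66,5.802519,2.177047,Sinking,Floating,-3.4977,4.98385
16,21.71,2.92,4.04,3.184143,2.743239,Floating,Floating,4.22665,3.0999
17,22.47,3.08,2.53,2.643532,1.933152,Floating,Floating,5.53729,4.3691
18,23.72,3.12,4.23,2.538462,3.013174,Floating,Floating,3.32625,5.9928
19,21.25,2.33,2.83,3.143128,2.408015,Floating,Floating,6.7572,3.1933
20,20.91,2.36,3.81,2.047177,2.329227,Floating,Floating,12.2276,11.17855
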