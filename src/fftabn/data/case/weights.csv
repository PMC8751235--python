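indicator,category,sv,iv,fp
Errors,,0.3324,,1.25e-3
Violations,,0.3456,,1.42e-3
Environmental factors,,0.3220,,1.12e-3
X1,Errors,0.2565,0.0853,8.41e-6
X2,Errors,0.2395,0.0796,6.27e-6
X3,Errors,0.2765,0.0919,1.15e-5
X4,Errors,0.2275,0.0756,5.01e-6
X5,Violations,0.1147,0.0396,2.19e-7
X6,Violations,0.1106,0.0382,1.80e-7
X7,Violations,0.1095,0.0378,1.70e-7
X8,Violations,0.1154,0.0399,2.28e-7
X9,Violations,0.1129,0.0390,2.01e-7
X10,Violations,0.1085,0.0375,1.63e-7
X11,Violations,0.1163,0.0402,2.37e-7
X12,Violations,0.1122,0.0388,1.96e-7
X13,Violations,0.1000,0.0346,1.05e-7
X14,Environmental factors,0.1619,0.0521,8.87e-7
X15,Environmental factors,0.1665,0.0536,1.02e-6
X16,Environmental factors,0.1648,0.0531,9.74e-7
X17,Environmental factors,0.1748,0.0563,1.29e-6
X18,Environmental factors,0.1724,0.0555,1.21e-6
X19,Environmental factors,0.1596,0.0514,8.30e-7
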