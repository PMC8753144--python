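z_m,rho_kg_m3,T_K,mfp_m
0,1.224999e+00,288.15,6.633232e-08
2000,1.006553e+00,275.15,8.072801e-08
4000,8.193463e-01,262.17,9.917301e-08
6000,6.601112e-01,249.19,1.230960e-07
8000,5.257860e-01,236.22,1.545439e-07
10000,4.135104e-01,223.25,1.965054e-07
12000,3.119381e-01,216.65,2.604909e-07
14000,2.278560e-01,216.65,3.566157e-07
16000,1.664708e-01,216.65,4.881157e-07
18000,1.216470e-01,216.65,6.679740e-07
20000,8.890990e-02,216.65,9.139257e-07
22000,6.450984e-02,218.57,1.259607e-06
24000,4.693787e-02,220.56,1.731161e-06
26000,3.425658e-02,222.54,2.372013e-06
28000,2.507629e-02,224.53,3.240393e-06
30000,1.841017e-02,226.51,4.413704e-06
32000,1.355515e-02,228.49,5.994550e-06
34000,9.887403e-03,233.74,8.218239e-06
36000,7.257919e-03,239.28,1.119564e-05
38000,5.366558e-03,244.82,1.514137e-05
40000,3.995678e-03,250.35,2.033623e-05
42000,2.994764e-03,255.88,2.713303e-05
44000,2.258851e-03,261.40,3.597273e-05
46000,1.714148e-03,266.92,4.740375e-05
48000,1.316700e-03,270.65,6.171264e-05
50000,1.026878e-03,270.65,7.913018e-05
52000,8.056162e-04,269.03,1.008632e-04
54000,6.390041e-04,263.52,1.271620e-04
56000,5.044504e-04,258.02,1.610803e-04
58000,3.962644e-04,252.52,2.050576e-04
60000,3.096778e-04,247.02,2.623922e-04
62000,2.407100e-04,241.53,3.375724e-04
64000,1.860505e-04,236.04,4.367471e-04
66000,1.429575e-04,230.55,5.684000e-04
68000,1.091693e-04,225.07,7.443216e-04
70000,8.282864e-05,219.58,9.810259e-04
71000,7.196515e-05,216.85,1.129117e-03
72000,6.237318e-05,214.26,1.302756e-03
73000,5.382387e-05,212.31,1.509684e-03
74000,4.638525e-05,210.35,1.751786e-03
75000,3.992107e-05,208.40,2.035442e-03
76000,3.431081e-05,206.45,2.368263e-03
77000,2.944797e-05,204.49,2.759343e-03
78000,2.523851e-05,202.54,3.219566e-03
79000,2.159954e-05,200.59,3.761981e-03
80000,1.845803e-05,198.64,4.402260e-03
81000,1.574977e-05,196.69,5.159254e-03
82000,1.341831e-05,194.74,6.055684e-03
83000,1.141415e-05,192.79,7.118977e-03
84000,9.693871e-06,190.84,8.382311e-03
85000,8.219500e-06,188.89,9.885886e-03
86000,6.958000e-06,186.87,1.167241e-02
87000,5.824287e-06,186.87,1.393966e-02
88000,4.875298e-06,186.87,1.664730e-02
89000,4.080933e-06,186.87,1.988086e-02
90000,3.416000e-06,186.87,2.374251e-02
91000,2.854989e-06,187.18,2.837258e-02
92000,2.386114e-06,187.49,3.390552e-02
93000,1.994242e-06,187.80,4.051737e-02
94000,1.666727e-06,188.11,4.841852e-02
95000,1.393000e-06,188.42,5.786034e-02
96000,1.161076e-06,189.75,6.925845e-02
97000,9.677650e-07,191.08,8.290146e-02
98000,8.066392e-07,192.42,9.923145e-02
99000,6.723397e-07,193.75,1.187775e-01
100000,5.604000e-07,195.08,1.421729e-01
101000,4.699840e-07,197.83,1.689034e-01
102000,3.941559e-07,200.58,2.006570e-01
103000,3.305621e-07,203.34,2.383769e-01
104000,2.772286e-07,206.09,2.831837e-01
105000,2.325000e-07,208.84,3.364080e-01
106000,1.952380e-07,215.07,3.988598e-01
107000,1.639478e-07,221.30,4.728964e-01
108000,1.376725e-07,227.54,5.606646e-01
109000,1.156081e-07,233.77,6.647094e-01
110000,9.708000e-08,240.00,7.880465e-01
111000,8.244703e-08,252.00,9.238964e-01
112000,7.001971e-08,264.00,1.083145e+00
113000,5.946556e-08,276.00,1.269818e+00
114000,5.050226e-08,288.00,1.488634e+00
115000,4.289000e-08,300.00,1.745124e+00
116000,3.760397e-08,312.00,1.983276e+00
117000,3.296942e-08,324.00,2.253899e+00
118000,2.890606e-08,336.00,2.561415e+00
119000,2.534349e-08,348.00,2.910849e+00
120000,2.222000e-08,360.00,3.307910e+00
121000,2.010000e-08,370.93,3.646197e+00
122000,1.818227e-08,381.85,4.019044e+00
123000,1.644751e-08,392.78,4.429980e+00
124000,1.487826e-08,403.71,4.882891e+00
125000,1.345873e-08,414.63,5.382061e+00
126000,1.217464e-08,425.56,5.932208e+00
127000,1.101306e-08,436.49,6.538534e+00
128000,9.962312e-09,447.42,7.206768e+00
129000,9.011813e-09,458.34,7.943226e+00
130000,8.152000e-09,469.27,8.754864e+00
131000,7.559080e-09,478.31,9.415970e+00
132000,7.009286e-09,487.34,1.012692e+01
133000,6.499479e-09,496.38,1.089148e+01
134000,6.026753e-09,505.41,1.171366e+01
135000,5.588409e-09,514.45,1.259782e+01
136000,5.181947e-09,523.49,1.354862e+01
137000,4.805048e-09,532.52,1.457106e+01
138000,4.455563e-09,541.56,1.567054e+01
139000,4.131496e-09,550.59,1.685285e+01
140000,3.831000e-09,559.63,1.812423e+01
141000,3.603327e-09,567.11,1.921878e+01
142000,3.389184e-09,574.58,2.037930e+01
143000,3.187768e-09,582.06,2.160975e+01
144000,2.998322e-09,589.53,2.291432e+01
145000,2.820134e-09,597.01,2.429748e+01
146000,2.652536e-09,604.49,2.576395e+01
147000,2.494898e-09,611.96,2.731873e+01
148000,2.346628e-09,619.44,2.896714e+01
149000,2.207170e-09,626.91,3.071478e+01
150000,2.076000e-09,634.39,3.256763e+01
151000,1.970611e-09,640.58,3.422252e+01
152000,1.870572e-09,646.77,3.596126e+01
153000,1.775612e-09,652.96,3.778810e+01
154000,1.685472e-09,659.15,3.970749e+01
155000,1.599909e-09,665.34,4.172410e+01
156000,1.518689e-09,671.53,4.384283e+01
157000,1.441592e-09,677.72,4.606885e+01
158000,1.368409e-09,683.91,4.840757e+01
159000,1.298941e-09,690.10,5.086468e+01
160000,1.233000e-09,696.29,5.344615e+01
161000,1.178039e-09,701.42,5.580630e+01
162000,1.125528e-09,706.55,5.827034e+01
163000,1.075357e-09,711.67,6.084283e+01
164000,1.027423e-09,716.80,6.352852e+01
165000,9.816259e-10,721.93,6.633238e+01
166000,9.378699e-10,727.06,6.925958e+01
167000,8.960644e-10,732.19,7.231554e+01
168000,8.561223e-10,737.31,7.550589e+01
169000,8.179606e-10,742.44,7.883652e+01
170000,7.815000e-10,747.57,8.231359e+01
171000,7.502159e-10,751.82,8.552544e+01
172000,7.201842e-10,756.07,8.886203e+01
173000,6.913546e-10,760.32,9.232818e+01
174000,6.636791e-10,764.57,9.592887e+01
175000,6.371115e-10,768.82,9.966932e+01
176000,6.116074e-10,773.07,1.035549e+02
177000,5.871243e-10,777.32,1.075912e+02
178000,5.636212e-10,781.57,1.117841e+02
179000,5.410590e-10,785.82,1.161396e+02
180000,5.194000e-10,790.07,1.206640e+02
181000,5.004402e-10,793.59,1.249384e+02
182000,4.821725e-10,797.12,1.293635e+02
183000,4.645716e-10,800.64,1.339445e+02
184000,4.476132e-10,804.17,1.386870e+02
185000,4.312739e-10,807.69,1.435966e+02
186000,4.155309e-10,811.21,1.486791e+02
187000,4.003627e-10,814.74,1.539406e+02
188000,3.857481e-10,818.26,1.593874e+02
189000,3.716671e-10,821.79,1.650259e+02
190000,3.581000e-10,825.31,1.708629e+02
191000,3.460225e-10,828.23,1.764132e+02
192000,3.343524e-10,831.16,1.821427e+02
193000,3.230758e-10,834.08,1.880574e+02
194000,3.121796e-10,837.01,1.941630e+02
195000,3.016508e-10,839.93,2.004657e+02
196000,2.914772e-10,842.86,2.069718e+02
197000,2.816466e-10,845.78,2.136879e+02
198000,2.721477e-10,848.71,2.206207e+02
199000,2.629690e-10,851.63,2.277771e+02
200000,2.541000e-10,854.56,2.351643e+02
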