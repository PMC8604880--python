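parameter,units,mouse,rat,monkey,human
FcRn_total,M,4.98E-05,4.98E-05,4.98E-05,4.98E-05
k_deg,1/h,26.6,26.6,26.6,26.6
FR,-,0.715,0.715,0.715,0.715
FR_B,-,0.715,0.715,0.715,0.715
kon_FcRn,1/M/h,8.06E+07,8.00E+08,7.92E+08,5.59E+08
koff_FcRn,1/h,6.55,144,46.8,23.9
V_P,L,9.44E-04,0.00906,0.187,3.13
V_Tv,L,8.06E-04,0.00789,0.151,1.68
V_Te,L,1.28E-04,0.00132,0.0286,0.335
V_Ti,L,0.00482,0.0483,0.976,11.1
V_Bv,L,1.07E-05,5.02E-05,0.00207,0.0319
V_BE_BBB,L,2.09E-06,9.82E-06,4.27E-04,0.00659
V_BE_BCSFB,L,3.37E-07,1.58E-06,4.27E-05,6.59E-04
V_Bi,L,8.73E-05,4.10E-04,0.0169,0.261
V_CSF,L,1.93E-05,2.97E-04,0.00926,0.143
V_L,L,1.13E-04,0.00115,0.0251,0.274
Q_T,L/h,0.361,2.88,20.9,160.5
Q_B,L/h,0.0118,0.0653,1.51,21.5
L_T,L/h,7.23E-04,0.00577,0.0419,0.321
L_B,L/h,2.16E-05,1.62E-04,0.00369,0.0345
Q_B_ECF,L/h,1.80E-06,3.00E-05,0.00123,0.0105
Q_B_CSF,L/h,1.98E-05,1.32E-04,0.00246,0.0240
k_CLUP_T,1/h,0.550,0.550,0.550,0.550
k_CLUP_B,1/h,0.0195,0.0195,0.0195,0.0195
CLUP_T,L/h,7.06E-05,7.26E-04,0.0157,0.184
CLUP_B,L/h,4.74E-08,2.23E-07,9.19E-06,1.42E-04
CLUP_BBB,L/h,4.08E-08,1.92E-07,8.35E-06,1.29E-04
CLUP_BCSFB,L/h,6.58E-09,3.09E-08,8.35E-07,1.29E-05
sigma_BBB,-,1,1,1,1
sigma_BCSFB,-,0.9973,0.9973,0.9973,0.9973
sigma_Tv,-,0.9172,0.9212,0.9239,0.9233
sigma_TL,-,0.2,0.2,0.2,0.2
sigma_ISF,-,0.2,0.2,0.2,0.2
sigma_CSF,-,0.2,0.2,0.2,0.2
SA_BBB,m^2,0.0155,0.0155,17,17
SA_BCSFB,m^2,0.0025,0.0025,1.7,1.7
f_BBB,-,0.861,0.861,0.909,0.909
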