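{
 "units": {
  "FcRn_total": "M",
  "k_deg": "1/h",
  "FR": "-",
  "FR_B": "-",
  "kon_FcRn": "1/M/h",
  "koff_FcRn": "1/h",
  "V_P": "L",
  "V_Tv": "L",
  "V_Te": "L",
  "V_Ti": "L",
  "V_Bv": "L",
  "V_BE_BBB": "L",
  "V_BE_BCSFB": "L",
  "V_Bi": "L",
  "V_CSF": "L",
  "V_L": "L",
  "Q_T": "L/h",
  "Q_B": "L/h",
  "L_T": "L/h",
  "L_B": "L/h",
  "Q_B_ECF": "L/h",
  "Q_B_CSF": "L/h",
  "k_CLUP_T": "1/h",
  "k_CLUP_B": "1/h",
  "CLUP_T": "L/h",
  "CLUP_B": "L/h",
  "CLUP_BBB": "L/h",
  "CLUP_BCSFB": "L/h",
  "sigma_BBB": "-",
  "sigma_BCSFB": "-",
  "sigma_Tv": "-",
  "sigma_TL": "-",
  "sigma_ISF": "-",
  "sigma_CSF": "-",
  "SA_BBB": "m^2",
  "SA_BCSFB": "m^2",
  "f_BBB": "-"
 },
 "species": {
  "mouse": {
   "FcRn_total": 4.98e-05,
   "k_deg": 26.6,
   "FR": 0.715,
   "FR_B": 0.715,
   "kon_FcRn": 80600000.0,
   "koff_FcRn": 6.55,
   "V_P": 0.000944,
   "V_Tv": 0.000806,
   "V_Te": 0.000128,
   "V_Ti": 0.00482,
   "V_Bv": 1.07e-05,
   "V_BE_BBB": 2.09e-06,
   "V_BE_BCSFB": 3.37e-07,
   "V_Bi": 8.73e-05,
   "V_CSF": 1.93e-05,
   "V_L": 0.000113,
   "Q_T": 0.361,
   "Q_B": 0.0118,
   "L_T": 0.000723,
   "L_B": 2.16e-05,
   "Q_B_ECF": 1.8e-06,
   "Q_B_CSF": 1.98e-05,
   "k_CLUP_T": 0.55,
   "k_CLUP_B": 0.0195,
   "CLUP_T": 7.06e-05,
   "CLUP_B": 4.74e-08,
   "CLUP_BBB": 4.08e-08,
   "CLUP_BCSFB": 6.58e-09,
   "sigma_BBB": 1.0,
   "sigma_BCSFB": 0.9973,
   "sigma_Tv": 0.9172,
   "sigma_TL": 0.2,
   "sigma_ISF": 0.2,
   "sigma_CSF": 0.2,
   "SA_BBB": 0.0155,
   "SA_BCSFB": 0.0025,
   "f_BBB": 0.861
  },
  "rat": {
   "FcRn_total": 4.98e-05,
   "k_deg": 26.6,
   "FR": 0.715,
   "FR_B": 0.715,
   "kon_FcRn": 800000000.0,
   "koff_FcRn": 144.0,
   "V_P": 0.00906,
   "V_Tv": 0.00789,
   "V_Te": 0.00132,
   "V_Ti": 0.0483,
   "V_Bv": 5.02e-05,
   "V_BE_BBB": 9.82e-06,
   "V_BE_BCSFB": 1.58e-06,
   "V_Bi": 0.00041,
   "V_CSF": 0.000297,
   "V_L": 0.00115,
   "Q_T": 2.88,
   "Q_B": 0.0653,
   "L_T": 0.00577,
   "L_B": 0.000162,
   "Q_B_ECF": 3e-05,
   "Q_B_CSF": 0.000132,
   "k_CLUP_T": 0.55,
   "k_CLUP_B": 0.0195,
   "CLUP_T": 0.000726,
   "CLUP_B": 2.23e-07,
   "CLUP_BBB": 1.92e-07,
   "CLUP_BCSFB": 3.09e-08,
   "sigma_BBB": 1.0,
   "sigma_BCSFB": 0.9973,
   "sigma_Tv": 0.9212,
   "sigma_TL": 0.2,
   "sigma_ISF": 0.2,
   "sigma_CSF": 0.2,
   "SA_BBB": 0.0155,
   "SA_BCSFB": 0.0025,
   "f_BBB": 0.861
  },
  "monkey": {
   "FcRn_total": 4.98e-05,
   "k_deg": 26.6,
   "FR": 0.715,
   "FR_B": 0.715,
   "kon_FcRn": 792000000.0,
   "koff_FcRn": 46.8,
   "V_P": 0.187,
   "V_Tv": 0.151,
   "V_Te": 0.0286,
   "V_Ti": 0.976,
   "V_Bv": 0.00207,
   "V_BE_BBB": 0.000427,
   "V_BE_BCSFB": 4.27e-05,
   "V_Bi": 0.0169,
   "V_CSF": 0.00926,
   "V_L": 0.0251,
   "Q_T": 20.9,
   "Q_B": 1.51,
   "L_T": 0.0419,
   "L_B": 0.00369,
   "Q_B_ECF": 0.00123,
   "Q_B_CSF": 0.00246,
   "k_CLUP_T": 0.55,
   "k_CLUP_B": 0.0195,
   "CLUP_T": 0.0157,
   "CLUP_B": 9.19e-06,
   "CLUP_BBB": 8.35e-06,
   "CLUP_BCSFB": 8.35e-07,
   "sigma_BBB": 1.0,
   "sigma_BCSFB": 0.9973,
   "sigma_Tv": 0.9239,
   "sigma_TL": 0.2,
   "sigma_ISF": 0.2,
   "sigma_CSF": 0.2,
   "SA_BBB": 17.0,
   "SA_BCSFB": 1.7,
   "f_BBB": 0.909
  },
  "human": {
   "FcRn_total": 4.98e-05,
   "k_deg": 26.6,
   "FR": 0.715,
   "FR_B": 0.715,
   "kon_FcRn": 559000000.0,
   "koff_FcRn": 23.9,
   "V_P": 3.13,
   "V_Tv": 1.68,
   "V_Te": 0.335,
   "V_Ti": 11.1,
   "V_Bv": 0.0319,
   "V_BE_BBB": 0.00659,
   "V_BE_BCSFB": 0.000659,
   "V_Bi": 0.261,
   "V_CSF": 0.143,
   "V_L": 0.274,
   "Q_T": 160.5,
   "Q_B": 21.5,
   "L_T": 0.321,
   "L_B": 0.0345,
   "Q_B_ECF": 0.0105,
   "Q_B_CSF": 0.024,
   "k_CLUP_T": 0.55,
   "k_CLUP_B": 0.0195,
   "CLUP_T": 0.184,
   "CLUP_B": 0.000142,
   "CLUP_BBB": 0.000129,
   "CLUP_BCSFB": 1.29e-05,
   "sigma_BBB": 1.0,
   "sigma_BCSFB": 0.9973,
   "sigma_Tv": 0.9233,
   "sigma_TL": 0.2,
   "sigma_ISF": 0.2,
   "sigma_CSF": 0.2,
   "SA_BBB": 17.0,
   "SA_BCSFB": 1.7,
   "f_BBB": 0.909
  }
 }
}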