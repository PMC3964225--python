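protein,C1,C2,C3,C4,C5,C7,C8,C9,C10,C6,N1,N2,N3,N4,N5,N6,N7,N8,N9,N10
AHNAK,1.52,1.73,1.40,1.36,1.12,1.73,1.35,1.66,1.58,0.84,0.90,0.89,0.89,0.99,1.18,0.82,1.21,1.00,1.05,1.23
ENO1,1.94,2.69,1.86,2.05,1.45,1.87,1.62,1.94,2.35,0.94,1.07,0.74,0.90,0.89,1.11,0.79,1.18,1.01,1.07,0.91
HSPB1,2.30,3.51,2.14,2.24,1.37,2.92,1.53,3.01,2.33,0.81,1.14,0.88,1.11,0.98,0.69,0.83,1.29,0.64,1.20,1.09
LDHA,1.94,2.64,2.97,3.60,2.55,4.93,3.92,3.20,4.12,0.78,0.53,1.07,0.80,1.03,0.97,0.63,1.13,0.99,1.04,0.97
ALDOA,1.72,1.51,1.16,1.15,1.33,2.36,1.46,1.74,1.87,0.82,0.81,0.73,0.87,0.98,1.21,0.71,1.08,0.95,1.00,1.09
ANXA2,,2.41,2.16,2.23,1.31,1.59,2.80,,1.93,0.95,,1.11,0.98,0.73,1.22,1.04,,,,
ANXA4,3.19,3.27,3.80,1.95,2.11,5.79,3.05,5.44,3.70,0.96,,0.66,0.92,0.96,0.82,0.66,0.64,0.83,0.98,0.96
ANXA5,1.62,1.82,1.52,2.36,1.12,1.83,1.73,1.60,2.27,0.82,0.84,0.99,0.88,0.94,1.38,0.68,1.15,0.97,1.05,0.95
CNDP2,1.53,1.56,2.01,1.42,1.34,2.30,1.30,2.51,1.91,1.01,1.11,0.90,0.93,1.02,0.90,0.86,0.93,0.94,1.09,0.97
CRYAB,2.20,3.83,2.34,1.84,0.90,3.65,1.33,2.59,1.99,,1.59,0.53,1.42,0.85,0.56,0.50,1.27,0.57,1.12,1.24
GAPDH,1.37,1.68,1.67,1.45,1.10,1.89,1.83,1.91,2.12,0.87,0.96,0.83,0.93,0.90,0.77,0.72,0.98,0.87,0.95,0.95
MIF,2.07,2.71,3.97,2.30,,2.47,1.69,2.32,,,1.23,1.54,,1.04,1.14,0.82,0.92,0.96,0.90,
PGK1,1.93,2.60,2.14,1.68,1.34,1.52,1.47,1.63,2.21,1.02,0.89,0.91,0.98,1.00,1.02,0.81,1.04,0.94,0.99,1.11
PKM2,2.73,3.47,,,2.38,,2.88,4.18,1.73,0.78,0.97,,0.70,,,0.63,1.12,0.87,0.98,
TPI1,1.69,2.11,1.54,1.44,1.41,2.10,1.69,2.17,1.68,0.97,0.99,0.78,0.93,1.05,1.04,0.87,1.11,0.93,0.99,0.95
HSPE1,0.72,0.54,0.45,0.22,,0.50,0.50,0.51,0.44,1.21,1.31,0.90,1.25,0.93,0.85,0.96,1.19,0.94,0.89,0.97
ACAA2,0.70,0.54,0.73,0.37,0.31,0.65,0.39,0.51,1.07,1.23,0.95,1.16,1.24,0.94,0.68,0.84,0.97,1.05,0.90,1.33
ACADM,0.34,0.34,0.43,0.28,0.46,0.44,0.56,0.37,0.59,1.27,1.15,0.91,1.18,0.93,0.73,1.05,1.20,0.96,0.95,1.00
ACAT1,,0.68,0.51,0.24,,0.33,0.33,0.34,0.50,1.19,1.21,1.35,1.14,0.96,0.76,0.96,0.97,0.92,0.87,1.11
ACO2,0.53,0.60,0.77,0.38,0.52,0.59,0.57,0.63,0.76,1.20,0.95,0.85,1.19,0.94,0.85,1.01,1.15,0.93,0.99,1.06
ACSF2,0.62,0.61,0.50,0.48,0.42,,,,,1.17,1.08,1.03,1.06,,,,,,,
ACY1,0.31,0.48,0.32,0.16,0.23,0.20,0.36,0.29,0.37,1.05,1.47,0.82,0.90,0.89,1.02,0.86,1.11,0.92,0.81,1.06
AKR1A1,0.36,0.40,1.10,0.52,0.38,0.57,0.55,0.56,0.96,0.84,1.00,1.12,1.16,1.01,0.71,0.62,1.14,0.88,0.98,1.15
ALDH2,0.37,,0.43,0.27,0.38,0.42,0.49,0.41,0.45,1.14,1.23,0.97,1.23,0.93,0.70,1.02,1.16,0.79,0.83,1.04
ALDH4A1,,,0.27,0.26,0.19,0.32,,0.38,0.45,1.17,1.06,0.94,1.43,0.90,0.44,0.91,0.92,0.89,0.88,0.99
ALDH6A1,0.28,0.30,0.24,0.21,0.25,0.30,0.30,0.26,0.49,1.34,1.14,0.98,1.27,0.91,0.75,0.94,1.23,0.96,0.82,1.07
ALDOB,0.47,0.71,0.43,0.43,0.64,0.42,0.47,0.35,0.53,1.14,0.94,1.10,1.34,1.15,0.44,0.95,0.96,0.78,1.06,1.05
ASS1,,,0.19,0.15,0.18,0.17,0.31,0.19,0.37,1.16,1.12,0.80,1.14,0.89,0.42,0.81,0.87,0.80,1.01,1.10
ATP5A1,,,0.60,0.37,0.40,0.63,0.59,0.60,0.72,1.15,,0.91,1.15,0.98,1.05,0.90,1.40,0.90,1.15,1.10
BDH2,,,0.56,0.50,0.37,0.48,0.55,0.39,0.89,0.94,,1.27,0.89,0.94,0.89,0.78,1.08,0.85,0.82,1.13
BHMT,,0.69,0.59,0.39,0.37,0.57,,0.61,,1.16,1.67,0.95,1.25,0.78,0.52,,,1.02,0.72,
CAT,0.57,0.61,,0.41,0.82,0.40,0.52,0.47,0.73,1.09,,,1.17,0.89,0.96,0.95,0.86,1.13,0.94,0.99
CTSB,,,0.45,0.35,,0.53,0.50,0.52,,0.71,,0.75,0.91,0.80,0.74,0.55,1.09,1.21,1.02,
CYCS,0.43,,0.64,0.43,,0.61,0.61,0.53,0.56,0.91,1.25,1.74,0.88,0.91,1.26,0.90,1.30,0.68,0.74,1.02
DDC,,,0.51,0.20,0.40,0.36,0.38,0.73,0.69,0.92,0.98,0.66,1.10,0.91,0.50,0.70,0.83,0.89,0.77,1.03
ECHS1,,,0.37,0.28,,0.33,0.34,0.31,0.54,1.21,1.04,1.34,1.33,0.96,0.69,1.04,1.15,1.02,0.95,1.14
ETFB,0.63,0.42,0.26,0.18,,0.41,,,0.60,,1.18,0.72,,0.97,0.77,,1.06,,,1.09
FBP1,,,0.57,0.35,0.33,,,0.57,0.60,1.16,,0.89,1.46,0.86,0.68,0.88,1.05,0.81,0.92,1.00
GATM,,,0.32,0.31,0.40,0.45,0.53,0.19,0.55,1.18,,1.08,1.09,0.93,0.48,0.96,0.91,0.93,0.91,0.96
GOT2,,,0.56,0.32,0.39,0.46,0.80,0.50,,1.07,0.81,1.31,1.09,0.97,1.04,0.93,1.18,0.89,0.87,
GPD1,,,0.47,0.19,0.23,0.40,0.44,0.51,0.61,1.12,1.07,0.72,1.19,1.05,0.54,0.94,0.96,1.12,1.08,0.96
HADH,,,0.32,0.28,,0.37,0.40,0.37,0.61,1.27,1.16,0.99,1.19,0.95,0.85,0.96,1.09,0.88,0.90,1.03
HNRNPA2B1,0.44,0.65,0.29,0.49,0.41,0.59,0.43,0.37,0.47,0.80,0.94,0.76,0.87,1.11,1.35,1.29,1.02,1.11,1.04,
IDH2,0.47,0.38,0.35,0.25,0.47,0.49,0.54,0.58,0.53,1.11,1.33,0.93,1.00,0.90,1.45,0.94,1.37,0.84,0.86,1.18
K4,0.59,,0.46,0.36,0.57,0.45,0.47,0.75,0.65,1.16,1.18,0.74,1.25,1.18,0.59,1.02,1.32,0.99,1.18,1.09
KHK,0.48,0.60,0.89,0.56,0.57,0.62,,0.61,1.05,1.11,1.02,0.87,1.14,1.05,0.63,0.94,1.05,0.94,0.89,0.99
LDHB,0.41,0.46,0.64,0.63,0.32,0.59,0.60,0.60,0.73,0.94,0.94,1.05,1.01,0.92,0.92,0.82,1.07,0.87,0.94,1.15
MDH2,0.64,0.50,0.67,0.33,0.39,0.54,0.59,0.51,0.59,1.08,1.06,1.20,1.12,0.94,1.06,0.88,1.07,0.90,0.77,0.98
PCK2,0.52,0.42,0.29,0.20,,0.24,0.31,0.27,0.45,1.24,1.22,1.05,1.61,0.96,0.41,1.05,0.94,0.89,0.89,1.05
PRDX3,,,0.30,0.21,0.35,0.52,0.46,0.41,0.55,1.17,1.04,0.65,1.09,0.95,1.12,0.95,1.08,0.89,0.89,1.03
SELENBP1,0.68,0.50,0.50,0.32,0.36,0.42,0.38,0.72,1.07,,0.95,0.94,0.93,0.98,0.98,1.23,1.01,0.84,1.04,
SORD,,,0.54,,0.34,0.30,0.31,,0.32,0.99,1.08,0.95,1.16,0.87,0.69,0.86,1.12,0.96,0.91,0.92
SPD1,0.61,0.54,0.55,0.29,0.29,0.46,0.50,0.50,0.73,1.26,1.10,0.91,1.26,0.92,0.85,0.88,1.04,0.96,0.96,1.22
TAGLN,0.97,,0.28,0.34,0.70,0.59,1.43,0.34,0.48,0.61,0.69,0.57,0.89,0.88,1.16,0.75,1.57,1.31,0.91,1.06
TP5B,,,0.65,0.39,0.58,0.62,,0.51,0.88,1.23,,0.62,1.25,0.96,1.17,0.95,1.31,0.84,0.97,1.03
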