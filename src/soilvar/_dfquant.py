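"""Frozen null-distribution quantiles of the Dickey-Fuller t-statistic.

Generated once by ``soilvar.stationarity.simulate_df_distribution`` with
T = 1000, 200,000 replicates per variant, seeds AR=20190611, ARD=20190612, TS=20190613.
Used for p-value interpolation; the 1/5/10% response-surface critical
values are computed separately and cross-checked against this grid.
"""

import numpy as np

DF_QUANT_PROBS = np.array([
    0.0005,
    0.0010,
    0.0025,
    0.0050,
    0.0075,
    0.0100,
    0.0150,
    0.0200,
    0.0250,
    0.0300,
    0.0350,
    0.0400,
    0.0450,
    0.0500,
    0.0550,
    0.0600,
    0.0650,
    0.0700,
    0.0750,
    0.0800,
    0.0850,
    0.0900,
    0.0950,
    0.1000,
    0.1050,
    0.1100,
    0.1150,
    0.1200,
    0.1250,
    0.1300,
    0.1350,
    0.1400,
    0.1450,
    0.1500,
    0.1550,
    0.1600,
    0.1650,
    0.1700,
    0.1750,
    0.1800,
    0.1850,
    0.1900,
    0.1950,
    0.2000,
    0.2050,
    0.2100,
    0.2150,
    0.2200,
    0.2250,
    0.2300,
    0.2350,
    0.2400,
    0.2450,
    0.2500,
    0.2550,
    0.2600,
    0.2650,
    0.2700,
    0.2750,
    0.2800,
    0.2850,
    0.2900,
    0.2950,
    0.3000,
    0.3050,
    0.3100,
    0.3150,
    0.3200,
    0.3250,
    0.3300,
    0.3350,
    0.3400,
    0.3450,
    0.3500,
    0.3550,
    0.3600,
    0.3650,
    0.3700,
    0.3750,
    0.3800,
    0.3850,
    0.3900,
    0.3950,
    0.4000,
    0.4050,
    0.4100,
    0.4150,
    0.4200,
    0.4250,
    0.4300,
    0.4350,
    0.4400,
    0.4450,
    0.4500,
    0.4550,
    0.4600,
    0.4650,
    0.4700,
    0.4750,
    0.4800,
    0.4850,
    0.4900,
    0.4950,
    0.5000,
    0.5050,
    0.5100,
    0.5150,
    0.5200,
    0.5250,
    0.5300,
    0.5350,
    0.5400,
    0.5450,
    0.5500,
    0.5550,
    0.5600,
    0.5650,
    0.5700,
    0.5750,
    0.5800,
    0.5850,
    0.5900,
    0.5950,
    0.6000,
    0.6050,
    0.6100,
    0.6150,
    0.6200,
    0.6250,
    0.6300,
    0.6350,
    0.6400,
    0.6450,
    0.6500,
    0.6550,
    0.6600,
    0.6650,
    0.6700,
    0.6750,
    0.6800,
    0.6850,
    0.6900,
    0.6950,
    0.7000,
    0.7050,
    0.7100,
    0.7150,
    0.7200,
    0.7250,
    0.7300,
    0.7350,
    0.7400,
    0.7450,
    0.7500,
    0.7550,
    0.7600,
    0.7650,
    0.7700,
    0.7750,
    0.7800,
    0.7850,
    0.7900,
    0.7950,
    0.8000,
    0.8050,
    0.8100,
    0.8150,
    0.8200,
    0.8250,
    0.8300,
    0.8350,
    0.8400,
    0.8450,
    0.8500,
    0.8550,
    0.8600,
    0.8650,
    0.8700,
    0.8750,
    0.8800,
    0.8850,
    0.8900,
    0.8950,
    0.9000,
    0.9050,
    0.9100,
    0.9150,
    0.9200,
    0.9250,
    0.9300,
    0.9350,
    0.9400,
    0.9450,
    0.9500,
    0.9550,
    0.9600,
    0.9650,
    0.9700,
    0.9750,
    0.9800,
    0.9850,
    0.9900,
    0.9925,
    0.9950,
    0.9975,
    0.9990,
    0.9995,
])

DF_QUANTILES = {
    "AR": np.array([
        -3.47909,
        -3.30597,
        -3.03082,
        -2.81649,
        -2.67485,
        -2.57223,
        -2.43483,
        -2.32450,
        -2.23842,
        -2.16545,
        -2.10007,
        -2.04616,
        -1.99663,
        -1.94933,
        -1.90622,
        -1.86601,
        -1.82865,
        -1.79321,
        -1.76037,
        -1.72882,
        -1.70031,
        -1.67142,
        -1.64445,
        -1.61892,
        -1.59460,
        -1.57068,
        -1.54820,
        -1.52538,
        -1.50388,
        -1.48456,
        -1.46528,
        -1.44431,
        -1.42513,
        -1.40686,
        -1.38715,
        -1.36977,
        -1.35302,
        -1.33580,
        -1.31744,
        -1.30159,
        -1.28520,
        -1.26886,
        -1.25328,
        -1.23806,
        -1.22287,
        -1.20724,
        -1.19271,
        -1.17832,
        -1.16366,
        -1.14949,
        -1.13547,
        -1.12121,
        -1.10679,
        -1.09364,
        -1.08025,
        -1.06761,
        -1.05497,
        -1.04217,
        -1.02919,
        -1.01633,
        -1.00412,
        -0.99182,
        -0.97987,
        -0.96692,
        -0.95537,
        -0.94366,
        -0.93130,
        -0.91941,
        -0.90720,
        -0.89538,
        -0.88370,
        -0.87203,
        -0.86067,
        -0.84945,
        -0.83831,
        -0.82667,
        -0.81510,
        -0.80283,
        -0.79158,
        -0.78001,
        -0.76819,
        -0.75706,
        -0.74620,
        -0.73484,
        -0.72347,
        -0.71181,
        -0.70061,
        -0.68928,
        -0.67774,
        -0.66615,
        -0.65426,
        -0.64259,
        -0.63090,
        -0.61913,
        -0.60844,
        -0.59648,
        -0.58545,
        -0.57373,
        -0.56186,
        -0.55052,
        -0.53810,
        -0.52643,
        -0.51393,
        -0.50157,
        -0.48886,
        -0.47658,
        -0.46476,
        -0.45265,
        -0.44063,
        -0.42846,
        -0.41594,
        -0.40345,
        -0.38969,
        -0.37751,
        -0.36462,
        -0.35105,
        -0.33720,
        -0.32364,
        -0.30987,
        -0.29671,
        -0.28310,
        -0.26968,
        -0.25629,
        -0.24298,
        -0.22924,
        -0.21570,
        -0.20237,
        -0.18769,
        -0.17349,
        -0.15932,
        -0.14540,
        -0.13043,
        -0.11539,
        -0.10104,
        -0.08689,
        -0.07205,
        -0.05632,
        -0.04144,
        -0.02686,
        -0.01162,
        0.00419,
        0.02023,
        0.03626,
        0.05216,
        0.06732,
        0.08391,
        0.10028,
        0.11548,
        0.13261,
        0.14880,
        0.16651,
        0.18337,
        0.19974,
        0.21675,
        0.23511,
        0.25299,
        0.27023,
        0.28892,
        0.30716,
        0.32567,
        0.34547,
        0.36517,
        0.38294,
        0.40268,
        0.42254,
        0.44212,
        0.46244,
        0.48249,
        0.50426,
        0.52588,
        0.54866,
        0.57161,
        0.59432,
        0.61721,
        0.64246,
        0.66759,
        0.69440,
        0.72090,
        0.74862,
        0.77569,
        0.80188,
        0.83017,
        0.86006,
        0.88893,
        0.92122,
        0.95471,
        0.98746,
        1.02194,
        1.05935,
        1.10264,
        1.14641,
        1.19029,
        1.24029,
        1.29053,
        1.34528,
        1.40504,
        1.47185,
        1.54637,
        1.63125,
        1.73254,
        1.86290,
        2.02495,
        2.13380,
        2.28997,
        2.54409,
        2.85642,
        3.06654,
    ]),
    "ARD": np.array([
        -4.27711,
        -4.10627,
        -3.85388,
        -3.66068,
        -3.53532,
        -3.44437,
        -3.30637,
        -3.20410,
        -3.12006,
        -3.05696,
        -2.99584,
        -2.94512,
        -2.89963,
        -2.85899,
        -2.82170,
        -2.78584,
        -2.75238,
        -2.72183,
        -2.69304,
        -2.66541,
        -2.63876,
        -2.61314,
        -2.58907,
        -2.56467,
        -2.54300,
        -2.52141,
        -2.50123,
        -2.48039,
        -2.45964,
        -2.44004,
        -2.42256,
        -2.40567,
        -2.38863,
        -2.37252,
        -2.35542,
        -2.33828,
        -2.32255,
        -2.30663,
        -2.29104,
        -2.27664,
        -2.26210,
        -2.24768,
        -2.23382,
        -2.22006,
        -2.20552,
        -2.19160,
        -2.17857,
        -2.16547,
        -2.15230,
        -2.13893,
        -2.12573,
        -2.11234,
        -2.09920,
        -2.08693,
        -2.07495,
        -2.06307,
        -2.05110,
        -2.03931,
        -2.02770,
        -2.01606,
        -2.00493,
        -1.99289,
        -1.98163,
        -1.97021,
        -1.95902,
        -1.94716,
        -1.93584,
        -1.92488,
        -1.91426,
        -1.90368,
        -1.89293,
        -1.88280,
        -1.87225,
        -1.86165,
        -1.85131,
        -1.84068,
        -1.83058,
        -1.82024,
        -1.81015,
        -1.80005,
        -1.78983,
        -1.78027,
        -1.77050,
        -1.76012,
        -1.75043,
        -1.74042,
        -1.73050,
        -1.72096,
        -1.71061,
        -1.70056,
        -1.69097,
        -1.68102,
        -1.67145,
        -1.66162,
        -1.65235,
        -1.64271,
        -1.63317,
        -1.62380,
        -1.61382,
        -1.60438,
        -1.59435,
        -1.58450,
        -1.57515,
        -1.56536,
        -1.55602,
        -1.54661,
        -1.53703,
        -1.52762,
        -1.51782,
        -1.50774,
        -1.49808,
        -1.48855,
        -1.47863,
        -1.46793,
        -1.45790,
        -1.44822,
        -1.43837,
        -1.42838,
        -1.41865,
        -1.40862,
        -1.39847,
        -1.38749,
        -1.37729,
        -1.36716,
        -1.35643,
        -1.34555,
        -1.33528,
        -1.32485,
        -1.31407,
        -1.30344,
        -1.29241,
        -1.28163,
        -1.27082,
        -1.25943,
        -1.24860,
        -1.23753,
        -1.22648,
        -1.21501,
        -1.20375,
        -1.19147,
        -1.17953,
        -1.16837,
        -1.15670,
        -1.14566,
        -1.13356,
        -1.12156,
        -1.10924,
        -1.09605,
        -1.08338,
        -1.07032,
        -1.05748,
        -1.04423,
        -1.02990,
        -1.01633,
        -1.00298,
        -0.98952,
        -0.97486,
        -0.95980,
        -0.94501,
        -0.93044,
        -0.91430,
        -0.89872,
        -0.88300,
        -0.86660,
        -0.84996,
        -0.83237,
        -0.81532,
        -0.79841,
        -0.78037,
        -0.76151,
        -0.74294,
        -0.72328,
        -0.70293,
        -0.68260,
        -0.66122,
        -0.63984,
        -0.61679,
        -0.59437,
        -0.57029,
        -0.54496,
        -0.51937,
        -0.49303,
        -0.46450,
        -0.43824,
        -0.40978,
        -0.37890,
        -0.34650,
        -0.31387,
        -0.27936,
        -0.24251,
        -0.20510,
        -0.16359,
        -0.12095,
        -0.07638,
        -0.02626,
        0.02544,
        0.08706,
        0.15578,
        0.23565,
        0.32808,
        0.44609,
        0.60101,
        0.71594,
        0.85211,
        1.06683,
        1.33497,
        1.55540,
    ]),
    "TS": np.array([
        -4.74343,
        -4.58605,
        -4.35800,
        -4.17279,
        -4.05510,
        -3.96412,
        -3.83691,
        -3.73735,
        -3.65850,
        -3.59911,
        -3.54695,
        -3.49812,
        -3.45426,
        -3.41436,
        -3.37763,
        -3.34448,
        -3.31218,
        -3.28342,
        -3.25692,
        -3.23061,
        -3.20502,
        -3.18018,
        -3.15823,
        -3.13549,
        -3.11358,
        -3.09280,
        -3.07208,
        -3.05105,
        -3.03294,
        -3.01528,
        -2.99719,
        -2.98005,
        -2.96326,
        -2.94621,
        -2.93065,
        -2.91447,
        -2.89870,
        -2.88379,
        -2.86921,
        -2.85423,
        -2.83955,
        -2.82559,
        -2.81186,
        -2.79775,
        -2.78429,
        -2.77049,
        -2.75705,
        -2.74387,
        -2.73141,
        -2.71892,
        -2.70731,
        -2.69486,
        -2.68377,
        -2.67154,
        -2.66007,
        -2.64834,
        -2.63692,
        -2.62554,
        -2.61481,
        -2.60298,
        -2.59211,
        -2.58169,
        -2.57120,
        -2.56091,
        -2.55090,
        -2.53973,
        -2.52962,
        -2.51892,
        -2.50875,
        -2.49859,
        -2.48828,
        -2.47852,
        -2.46885,
        -2.45901,
        -2.44910,
        -2.43949,
        -2.42965,
        -2.42021,
        -2.41096,
        -2.40107,
        -2.39203,
        -2.38231,
        -2.37322,
        -2.36375,
        -2.35452,
        -2.34526,
        -2.33625,
        -2.32755,
        -2.31797,
        -2.30836,
        -2.29887,
        -2.28966,
        -2.28036,
        -2.27138,
        -2.26273,
        -2.25370,
        -2.24455,
        -2.23554,
        -2.22645,
        -2.21796,
        -2.20875,
        -2.20016,
        -2.19109,
        -2.18184,
        -2.17271,
        -2.16385,
        -2.15470,
        -2.14593,
        -2.13657,
        -2.12762,
        -2.11829,
        -2.10968,
        -2.10110,
        -2.09185,
        -2.08310,
        -2.07388,
        -2.06465,
        -2.05591,
        -2.04752,
        -2.03844,
        -2.02905,
        -2.01997,
        -2.01141,
        -2.00232,
        -1.99314,
        -1.98373,
        -1.97462,
        -1.96569,
        -1.95678,
        -1.94754,
        -1.93812,
        -1.92887,
        -1.91931,
        -1.90904,
        -1.89936,
        -1.88957,
        -1.87985,
        -1.87023,
        -1.86047,
        -1.85081,
        -1.84020,
        -1.82952,
        -1.81923,
        -1.80904,
        -1.79896,
        -1.78814,
        -1.77704,
        -1.76677,
        -1.75597,
        -1.74500,
        -1.73371,
        -1.72254,
        -1.71167,
        -1.70129,
        -1.68980,
        -1.67873,
        -1.66702,
        -1.65544,
        -1.64341,
        -1.63116,
        -1.61860,
        -1.60595,
        -1.59275,
        -1.57878,
        -1.56592,
        -1.55289,
        -1.53956,
        -1.52525,
        -1.51120,
        -1.49717,
        -1.48250,
        -1.46697,
        -1.45174,
        -1.43671,
        -1.42094,
        -1.40392,
        -1.38631,
        -1.36808,
        -1.34981,
        -1.33123,
        -1.31064,
        -1.28953,
        -1.26743,
        -1.24373,
        -1.22005,
        -1.19383,
        -1.16722,
        -1.14119,
        -1.11362,
        -1.08285,
        -1.05136,
        -1.01548,
        -0.97981,
        -0.93936,
        -0.89597,
        -0.84797,
        -0.79412,
        -0.73363,
        -0.65922,
        -0.57456,
        -0.46921,
        -0.32092,
        -0.22819,
        -0.10295,
        0.10911,
        0.38508,
        0.57938,
    ]),
}
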