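# synthetic crossover trial fixture 'small': 6 subjects, seed 101
ID,TIME,AMT,DV,EVID,MDV,OCC,FOOD,CAL
1,0,250,0,1,1,1,0,0
1,0,0,0,0,1,1,0,0
1,1,0,0.0456009,0,0,1,0,0
1,2,0,0.276179,0,0,1,0,0
1,3,0,0.455557,0,0,1,0,0
1,4,0,0.640956,0,0,1,0,0
1,5,0,0.904965,0,0,1,0,0
1,6,0,0.398197,0,0,1,0,0
1,8,0,1.97466,0,0,1,0,0
1,10,0,3.26254,0,0,1,0,0
1,12,0,1.57989,0,0,1,0,0
1,24,0,2.24066,0,0,1,0,0
1,48,0,1.89804,0,0,1,0,0
1,72,0,1.22793,0,0,1,0,0
1,0,250,0,1,1,2,1,686.3
1,0,0,0,0,1,2,1,0
1,1,0,0.13613,0,0,2,1,0
1,2,0,0.366226,0,0,2,1,0
1,3,0,0.673985,0,0,2,1,0
1,4,0,0.157528,0,0,2,1,0
1,5,0,2.05815,0,0,2,1,0
1,6,0,2.70392,0,0,2,1,0
1,8,0,5.66036,0,0,2,1,0
1,10,0,7.62295,0,0,2,1,0
1,12,0,6.72691,0,0,2,1,0
1,24,0,0.0101597,0,0,2,1,0
1,48,0,0.922326,0,0,2,1,0
1,72,0,1.7902,0,0,2,1,0
1,0,250,0,1,1,3,2,1280
1,0,0,0,0,1,3,2,0
1,1,0,0.255821,0,0,3,2,0
1,2,0,0.593073,0,0,3,2,0
1,3,0,1.2885,0,0,3,2,0
1,4,0,2.48017,0,0,3,2,0
1,5,0,2.91993,0,0,3,2,0
1,6,0,0.451415,0,0,3,2,0
1,8,0,11.5534,0,0,3,2,0
1,10,0,10.981,0,0,3,2,0
1,12,0,12.9356,0,0,3,2,0
1,24,0,4.766,0,0,3,2,0
1,48,0,2.35609,0,0,3,2,0
1,72,0,0.312076,0,0,3,2,0
2,0,250,0,1,1,1,0,0
2,0,0,0,0,1,1,0,0
2,1,0,0.0145725,0,0,1,0,0
2,2,0,0.0237004,0,0,1,0,0
2,3,0,0.0369243,0,0,1,0,0
2,4,0,0.0174209,0,0,1,0,0
2,5,0,0.0891466,0,0,1,0,0
2,6,0,0.0889417,0,0,1,0,0
2,8,0,0.0614201,0,0,1,0,0
2,10,0,0.0420721,0,0,1,0,0
2,12,0,0.103548,0,0,1,0,0
2,24,0,0.0909171,0,0,1,0,0
2,48,0,0.0148918,0,0,1,0,0
2,72,0,0.00450356,0,0,1,0,0
2,0,250,0,1,1,2,1,686.3
2,0,0,0,0,1,2,1,0
2,1,0,0.0516007,0,0,2,1,0
2,2,0,0.166488,0,0,2,1,0
2,3,0,0.22867,0,0,2,1,0
2,4,0,0.631019,0,0,2,1,0
2,5,0,1.13882,0,0,2,1,0
2,6,0,0.31258,0,0,2,1,0
2,8,0,1.56451,0,0,2,1,0
2,10,0,0.62255,0,0,2,1,0
2,12,0,0.58753,0,0,2,1,0
2,24,0,0.127202,0,0,2,1,0
2,48,0,0.147844,0,0,2,1,0
2,72,0,0.038546,0,0,2,1,0
2,0,250,0,1,1,3,2,1280
2,0,0,0,0,1,3,2,0
2,1,0,0.0966486,0,0,3,2,0
2,2,0,0.154921,0,0,3,2,0
2,3,0,0.302783,0,0,3,2,0
2,4,0,0.40897,0,0,3,2,0
2,5,0,0.748397,0,0,3,2,0
2,6,0,1.18156,0,0,3,2,0
2,8,0,0.55568,0,0,3,2,0
2,10,0,0.318873,0,0,3,2,0
2,12,0,0.0766721,0,0,3,2,0
2,24,0,0.323944,0,0,3,2,0
2,48,0,0.0533813,0,0,3,2,0
2,72,0,0.0041052,0,0,3,2,0
3,0,250,0,1,1,1,0,0
3,0,0,0,0,1,1,0,0
3,1,0,0.230745,0,0,1,0,0
3,2,0,2.30275,0,0,1,0,0
3,3,0,1.33033,0,0,1,0,0
3,4,0,4.65289,0,0,1,0,0
3,5,0,3.03345,0,0,1,0,0
3,6,0,7.29855,0,0,1,0,0
3,8,0,6.43912,0,0,1,0,0
3,10,0,8.53221,0,0,1,0,0
3,12,0,26.2052,0,0,1,0,0
3,24,0,13.2062,0,0,1,0,0
3,48,0,16.7418,0,0,1,0,0
3,72,0,1.48863,0,0,1,0,0
3,0,250,0,1,1,2,1,686.3
3,0,0,0,0,1,2,1,0
3,1,0,0.48476,0,0,2,1,0
3,2,0,0.429604,0,0,2,1,0
3,3,0,3.22993,0,0,2,1,0
3,4,0,6.50728,0,0,2,1,0
3,5,0,9.44374,0,0,2,1,0
3,6,0,7.1898,0,0,2,1,0
3,8,0,1.5186,0,0,2,1,0
3,10,0,22.6479,0,0,2,1,0
3,12,0,21.1521,0,0,2,1,0
3,24,0,5.06829,0,0,2,1,0
3,48,0,7.39936,0,0,2,1,0
3,72,0,4.68991,0,0,2,1,0
3,0,250,0,1,1,3,2,1280
3,0,0,0,0,1,3,2,0
3,1,0,1.30518,0,0,3,2,0
3,2,0,5.96275,0,0,3,2,0
3,3,0,3.23445,0,0,3,2,0
3,4,0,7.21981,0,0,3,2,0
3,5,0,27.327,0,0,3,2,0
3,6,0,31.2839,0,0,3,2,0
3,8,0,55.0938,0,0,3,2,0
3,10,0,3.47289,0,0,3,2,0
3,12,0,16.2124,0,0,3,2,0
3,24,0,63.5097,0,0,3,2,0
3,48,0,6.71263,0,0,3,2,0
3,72,0,6.10047,0,0,3,2,0
4,0,250,0,1,1,1,0,0
4,0,0,0,0,1,1,0,0
4,1,0,0.0201122,0,0,1,0,0
4,2,0,0.09099,0,0,1,0,0
4,3,0,0.00370383,0,0,1,0,0
4,4,0,0.11469,0,0,1,0,0
4,5,0,0.0704768,0,0,1,0,0
4,6,0,0.282261,0,0,1,0,0
4,8,0,0.984348,0,0,1,0,0
4,10,0,1.43482,0,0,1,0,0
4,12,0,1.51334,0,0,1,0,0
4,24,0,1.46707,0,0,1,0,0
4,48,0,0.571858,0,0,1,0,0
4,72,0,0.252103,0,0,1,0,0
4,0,250,0,1,1,2,1,686.3
4,0,0,0,0,1,2,1,0
4,1,0,0.0390339,0,0,2,1,0
4,2,0,0.159383,0,0,2,1,0
4,3,0,0.217252,0,0,2,1,0
4,4,0,1.46926,0,0,2,1,0
4,5,0,0.43319,0,0,2,1,0
4,6,0,1.18095,0,0,2,1,0
4,8,0,1.41986,0,0,2,1,0
4,10,0,6.70701,0,0,2,1,0
4,12,0,1.40542,0,0,2,1,0
4,24,0,4.31914,0,0,2,1,0
4,48,0,3.66243,0,0,2,1,0
4,72,0,0.190086,0,0,2,1,0
4,0,250,0,1,1,3,2,1280
4,0,0,0,0,1,3,2,0
4,1,0,0.0111674,0,0,3,2,0
4,2,0,0.384813,0,0,3,2,0
4,3,0,0.310101,0,0,3,2,0
4,4,0,1.14597,0,0,3,2,0
4,5,0,1.28561,0,0,3,2,0
4,6,0,1.25945,0,0,3,2,0
4,8,0,2.77339,0,0,3,2,0
4,10,0,1.70043,0,0,3,2,0
4,12,0,3.8073,0,0,3,2,0
4,24,0,0.444758,0,0,3,2,0
4,48,0,0.597151,0,0,3,2,0
4,72,0,0.760024,0,0,3,2,0
5,0,250,0,1,1,1,0,0
5,0,0,0,0,1,1,0,0
5,1,0,0.127478,0,0,1,0,0
5,2,0,0.0156044,0,0,1,0,0
5,3,0,0.687875,0,0,1,0,0
5,4,0,0.886505,0,0,1,0,0
5,5,0,0.674542,0,0,1,0,0
5,6,0,1.06201,0,0,1,0,0
5,8,0,2.10355,0,0,1,0,0
5,10,0,1.09487,0,0,1,0,0
5,12,0,0.140761,0,0,1,0,0
5,24,0,2.21615,0,0,1,0,0
5,48,0,0.572976,0,0,1,0,0
5,72,0,0.533592,0,0,1,0,0
5,0,250,0,1,1,2,1,686.3
5,0,0,0,0,1,2,1,0
5,1,0,0.185752,0,0,2,1,0
5,2,0,0.346915,0,0,2,1,0
5,3,0,0.565481,0,0,2,1,0
5,4,0,1.1583,0,0,2,1,0
5,5,0,1.1733,0,0,2,1,0
5,6,0,1.78125,0,0,2,1,0
5,8,0,0.930401,0,0,2,1,0
5,10,0,0.374362,0,0,2,1,0
5,12,0,2.10329,0,0,2,1,0
5,24,0,1.91857,0,0,2,1,0
5,48,0,0.779366,0,0,2,1,0
5,72,0,0.143757,0,0,2,1,0
5,0,250,0,1,1,3,2,1280
5,0,0,0,0,1,3,2,0
5,1,0,0.0360798,0,0,3,2,0
5,2,0,0.0711452,0,0,3,2,0
5,3,0,0.127404,0,0,3,2,0
5,4,0,1.3399,0,0,3,2,0
5,5,0,1.0615,0,0,3,2,0
5,6,0,2.78159,0,0,3,2,0
5,8,0,0.601234,0,0,3,2,0
5,10,0,4.08598,0,0,3,2,0
5,12,0,1.99996,0,0,3,2,0
5,24,0,4.47851,0,0,3,2,0
5,48,0,2.43029,0,0,3,2,0
5,72,0,0.782878,0,0,3,2,0
6,0,250,0,1,1,1,0,0
6,0,0,0,0,1,1,0,0
6,1,0,0.0176109,0,0,1,0,0
6,2,0,0.0808963,0,0,1,0,0
6,3,0,0.186646,0,0,1,0,0
6,4,0,0.227695,0,0,1,0,0
6,5,0,0.485875,0,0,1,0,0
6,6,0,0.537553,0,0,1,0,0
6,8,0,0.550482,0,0,1,0,0
6,10,0,0.624802,0,0,1,0,0
6,12,0,0.676553,0,0,1,0,0
6,24,0,0.315104,0,0,1,0,0
6,48,0,0.052097,0,0,1,0,0
6,72,0,0.0361513,0,0,1,0,0
6,0,250,0,1,1,2,1,686.3
6,0,0,0,0,1,2,1,0
6,1,0,0.062782,0,0,2,1,0
6,2,0,0.519339,0,0,2,1,0
6,3,0,0.549846,0,0,2,1,0
6,4,0,1.76961,0,0,2,1,0
6,5,0,2.02408,0,0,2,1,0
6,6,0,5.3407,0,0,2,1,0
6,8,0,3.24698,0,0,2,1,0
6,10,0,4.09781,0,0,2,1,0
6,12,0,5.27769,0,0,2,1,0
6,24,0,6.05943,0,0,2,1,0
6,48,0,0.66035,0,0,2,1,0
6,72,0,1.29378,0,0,2,1,0
6,0,250,0,1,1,3,2,1280
6,0,0,0,0,1,3,2,0
6,1,0,0.0669769,0,0,3,2,0
6,2,0,0.209496,0,0,3,2,0
6,3,0,0.373074,0,0,3,2,0
6,4,0,1.07407,0,0,3,2,0
6,5,0,1.36347,0,0,3,2,0
6,6,0,0.91831,0,0,3,2,0
6,8,0,1.1904,0,0,3,2,0
6,10,0,1.03671,0,0,3,2,0
6,12,0,0.766708,0,0,3,2,0
6,24,0,0.608365,0,0,3,2,0
6,48,0,0.27991,0,0,3,2,0
6,72,0,0.212306,0,0,3,2,0
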