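dose_uM,inhibition,agent
0.02,0.010606,drugA
0.02,0.010749,drugA
0.02,0.034002,drugA
0.050198,0.058473,drugA
0.050198,0.052375,drugA
0.050198,0.039313,drugA
0.125992,0.227336,drugA
0.125992,0.169306,drugA
0.125992,0.156071,drugA
0.316228,0.301325,drugA
0.316228,0.37177,drugA
0.316228,0.493293,drugA
0.793701,0.712171,drugA
0.793701,0.722865,drugA
0.793701,0.713326,drugA
1.99211,0.832177,drugA
1.99211,0.850484,drugA
1.99211,0.882002,drugA
5.0,0.91682,drugA
5.0,0.886706,drugA
5.0,0.921111,drugA
0.02,0.001837,drugB
0.02,0.021633,drugB
0.02,0.027394,drugB
0.050198,0.012004,drugB
0.050198,0.016601,drugB
0.050198,0.008508,drugB
0.125992,0.044007,drugB
0.125992,0.091358,drugB
0.125992,0.117679,drugB
0.316228,0.141834,drugB
0.316228,0.181241,drugB
0.316228,0.227689,drugB
0.793701,0.411123,drugB
0.793701,0.471588,drugB
0.793701,0.44523,drugB
1.99211,0.70294,drugB
1.99211,0.62335,drugB
1.99211,0.714907,drugB
5.0,0.762692,drugB
5.0,0.870297,drugB
5.0,0.829528,drugB
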