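dose_mGy,net_pixel_value
0,0
2,2593
4,4914
6,7114
8,9047
10,10328
15,13295
20,15672
25,17911
50,22275
75,24957
100,26567
150,28078
200,28944
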