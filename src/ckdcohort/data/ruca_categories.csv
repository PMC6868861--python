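ruca_code,category
1.0,urban
1.1,urban
2.0,urban
2.1,urban
3.0,urban
4.0,rural
4.1,urban
4.2,rural
5.0,rural
5.1,urban
5.2,rural
6.0,rural
6.1,rural
7.0,rural
7.1,urban
7.2,rural
7.3,rural
7.4,rural
8.0,rural
8.1,urban
8.2,rural
8.3,rural
8.4,rural
9.0,rural
9.1,rural
9.2,rural
10.0,rural
10.1,urban
10.2,rural
10.3,rural
10.4,rural
10.5,rural
10.6,rural
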