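label,percent
96b,20
97a,19
97b,22.1
98a,25
98b,35.1
99a,44.1
99b,50.1
00a,54.2
00b,48.1
01a,57.1
01b,54.3
02a,54.3
02b,52.8
03a,58.7
03b,62.9
04a,61.1
04b,66.3
05a,65.6
05b,74.9
06a,69.9
06b,73.2
07a,70.5
07b,70.5
08a,69.4
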