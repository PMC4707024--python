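label,percent
96b,
97a,
97b,
98a,
98b,
99a,24
99b,24
00a,29
00b,23
01a,30
01b,31
02a,29
02b,32
03a,30.9
03b,38.9
04a,36.2
04b,39.2
05a,44.4
05b,45.7
06a,45.5
06b,52.7
07a,56.3
07b,56.7
08a,60.4
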