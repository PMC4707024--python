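label,percent
96b,
97a,
97b,
98a,31
98b,32
99a,33
99b,37
00a,40
00b,40
01a,46
01b,48
02a,46
02b,46
03a,47.8
03b,50.7
04a,49.6
04b,49
05a,53.4
05b,48.2
06a,52.5
06b,52.8
07a,54.1
07b,53
08a,53
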