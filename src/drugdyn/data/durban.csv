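label,percent
96b,27
97a,31
97b,34
98a,35
98b,33
99a,38
99b,35
00a,40
00b,40
01a,41
01b,42
02a,43
02b,42
03a,43.7
03b,44.6
04a,42.1
04b,46
05a,48.9
05b,45.4
06a,48.6
06b,46
07a,50.2
07b,55.2
08a,50.5
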