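overall_ws,overall_wp,top_ws,top_wp,bot_ws,bot_wp,tll_printed
17.58,28.98,9.44,61.42,22.43,10.47,52.58
18.95,29.09,9.34,63.92,24.13,10.05,55.86
20.48,29.05,9.43,65.94,25.90,9.86,58.45
21.91,29.11,9.43,68.52,27.51,9.26,61.96
23.13,29.12,9.45,71.32,29.79,8.41,66.12
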