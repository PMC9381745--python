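drug,overall_ws,overall_wp,K,ee_printed
ibuprofen,17.58,28.98,8.87,89.87
ibuprofen,18.95,29.09,9.51,90.49
ibuprofen,20.48,29.05,10.35,91.19
ibuprofen,21.91,29.11,11.93,92.27
ibuprofen,23.13,29.12,14.20,93.42
acetaminophen,17.58,28.98,6.66,86.95
acetaminophen,18.95,29.09,7.31,87.95
acetaminophen,20.48,29.05,8.14,89.06
acetaminophen,21.91,29.11,9.72,90.67
acetaminophen,23.13,29.12,11.99,92.30
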