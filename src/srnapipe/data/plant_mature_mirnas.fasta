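>miR156
TGACAGAAGAGAGTGAGCAC
>miR159
TTTGGATTGAAGGGAGCTCTA
>miR160
TGCCTGGCTCCCTGTATGCCA
>miR164
TGGAGAAGCAGGGCACGTGCA
>miR166
TCGGACCAGGCTTCATTCCCC
>miR167
TGAAGCTGCCAGCATGATCTA
>miR168
TCGCTTGGTGCAGGTCGGGAA
>miR169
CAGCCAAGGATGACTTGCCGA
>miR171
TGATTGAGCCGCGCCAATATC
>miR172
AGAATCTTGATGATGCTGCAT
>miR319
TTGGACTGAAGGGAGCTCCCT
>miR390
AAGCTCAGGAGGGATAGCGCC
>miR393
TCCAAAGGGATCGCATTGATCC
>miR396
TTCCACAGCTTTCTTGAACTG
>miR399
TGCCAAAGGAGATTTGCCCTG
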