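>Primer1_F target=L1HS
GACATCTACACCGAAAACCC
>Primer1_R target=L1HS
TCGTCAAAATCATTCTCCATCC
>Primer2_F target=L1PA3
ACCAGCCACTGCAAAATC
>Primer2_R target=L1PA3
CCAATTTGCCAGTCTGTGTC
>Primer3_F target=L1PA4
ATGCACAAGCCTCAGTAGCC
>Primer3_R target=L1PA4
TCCATTCTCCCCGTCACTTTC
>Primer4_F target=L1PA5
TCCACACCAAAACCCCATC
>Primer4_R target=L1PA5
CTCGTCAAAGTCATTCTCCATC
>Primer5_F target=L1PA16
GACAAAGGTGACATTACAAC
>Primer5_R target=L1PA16
CTTGGGAGATTGTGTGTTTC
>Primer6_F target=L1PA17
AGAATGAAACTGGACCCCTA
>Primer6_R target=L1PA17
GTCCAGAAGAGTATTTCCTA
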