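>ins_A1 bovine insulin chain A (dimer copy 1)
GIVEQCCASVCSLYQLENYCN
>ins_B1 bovine insulin chain B (dimer copy 1)
FVNQHLCGSHLVEALYLVCGERGFFYTPKA
>ins_A2 bovine insulin chain A (dimer copy 2)
GIVEQCCASVCSLYQLENYCN
>ins_B2 bovine insulin chain B (dimer copy 2)
FVNQHLCGSHLVEALYLVCGERGFFYTPKA
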