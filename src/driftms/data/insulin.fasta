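>insulin_chain_A bovine insulin A chain (21 aa)
GIVEQCCASVCSLYQLENYCN
>insulin_chain_B bovine insulin B chain (30 aa)
FVNQHLCGSHLVEALYLVCGERGFFYTPKA
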