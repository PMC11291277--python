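"""Dayhoff (1978) empirical amino-acid replacement model constants.

Exchangeabilities are the classic integer-scaled symmetric rates in the
conventional ARNDCQEGHILKMFPSTWYV residue order; frequencies are the
matching equilibrium composition. Scaling is irrelevant downstream
because the generator is renormalized to one expected substitution per
unit branch length.
"""

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

DAYHOFF_FREQUENCIES = [
    0.0871269129, 0.0409039591, 0.0404319596, 0.0468719531,
    0.0334739665, 0.0382549617, 0.0495299505, 0.0886119114,
    0.0336179664, 0.0368859631, 0.0853569146, 0.0804819195,
    0.0147529852, 0.0397719602, 0.0506799493, 0.0695769304,
    0.0585419415, 0.0104939895, 0.0299159701, 0.0647179353,
]

DAYHOFF_EXCHANGEABILITIES = [
    [0, 27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371, 0, 24, 208],
    [27, 0, 32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154, 26, 201, 8, 24],
    [98, 32, 0, 905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42, 495, 229, 23, 95, 15],
    [120, 0, 905, 0, 0, 134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95, 66, 0, 0, 18],
    [36, 23, 0, 0, 0, 0, 0, 11, 28, 44, 0, 0, 0, 0, 19, 161, 16, 0, 96, 49],
    [89, 246, 103, 134, 0, 0, 716, 28, 606, 18, 73, 153, 114, 0, 153, 56, 53, 0, 0, 35],
    [198, 1, 148, 1153, 0, 716, 0, 81, 43, 61, 11, 83, 30, 0, 51, 79, 34, 0, 22, 37],
    [240, 9, 139, 125, 11, 28, 81, 0, 10, 0, 7, 27, 17, 15, 34, 234, 30, 0, 0, 54],
    [23, 240, 535, 86, 28, 606, 43, 10, 0, 7, 44, 26, 0, 48, 94, 35, 22, 27, 127, 44],
    [65, 64, 77, 24, 44, 18, 61, 0, 7, 0, 257, 46, 336, 196, 12, 24, 192, 0, 37, 889],
    [41, 15, 34, 0, 0, 73, 11, 7, 44, 257, 0, 18, 527, 157, 32, 17, 33, 46, 28, 175],
    [26, 464, 318, 71, 0, 153, 83, 27, 26, 46, 18, 0, 243, 0, 33, 96, 136, 0, 13, 10],
    [72, 90, 1, 0, 0, 114, 30, 17, 0, 336, 527, 243, 0, 92, 17, 62, 104, 0, 0, 258],
    [18, 14, 14, 0, 0, 0, 0, 15, 48, 196, 157, 0, 92, 0, 11, 46, 13, 76, 698, 12],
    [250, 103, 42, 13, 19, 153, 51, 34, 94, 12, 32, 33, 17, 11, 0, 245, 78, 0, 0, 48],
    [409, 154, 495, 95, 161, 56, 79, 234, 35, 24, 17, 96, 62, 46, 245, 0, 550, 75, 34, 30],
    [371, 26, 229, 66, 16, 53, 34, 30, 22, 192, 33, 136, 104, 13, 78, 550, 0, 0, 42, 157],
    [0, 201, 23, 0, 0, 0, 0, 0, 27, 0, 46, 0, 0, 76, 0, 75, 0, 0, 61, 0],
    [24, 8, 95, 0, 96, 0, 22, 0, 127, 37, 28, 13, 0, 698, 0, 34, 42, 61, 0, 28],
    [208, 24, 15, 18, 49, 35, 37, 54, 44, 889, 175, 10, 258, 12, 48, 30, 157, 0, 28, 0],
]
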