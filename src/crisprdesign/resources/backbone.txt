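# Invariant sgRNA scaffold (tracrRNA-derived backbone), written as DNA.
# Used by the self-complementarity screen for guide-vs-backbone stems.
GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCTTTT
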