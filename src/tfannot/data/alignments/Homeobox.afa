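>Homeobox_m1
RRKRTTFTKEQLEELEKEFHFNRYLTRRRRIELAHSLNLTERQVKIWFQNRRMKWKKE
>Homeobox_m2
RRFRTTFLNEQLEELEKEFHFNRYLTRRRREELAHSLNLTERQPKIWFQNRRMKWKKT
>Homeobox_m3
RRKRTTFTKFQLVELEKGFHFNRYLTRRRRIELAHILNLTERNVKIWFQNRRMKWKKQ
>Homeobox_m4
RRKRTDFTKEQLEVLEKEFHFNEYLTHRRRIELTHSLNLTERQVKIWFSNRRMKWKKE
>Homeobox_m5
RRKRTTFTKEQLEELEKEFHFNRYLTRRRRIELAHSLNHYERQVKIWFQNRRMKWKKP
>Homeobox_m6
CRKRTTFTKEQLEELEKEFHFNRYLTRRRRIELAHSLNLRERQVKIWFQNRRMKWKKE
>Homeobox_m7
RRKRTTFTKEQLEELEKEFHRNRYLTRRRRIELAHSHNLTERQVKIWFQNRRMKWKKE
>Homeobox_m8
RRKRTTFTKEQGEEDEKEFHFNRYLTRRRRIELAHSLGLTHRQVKILFQNRRMKWKAE
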