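>B3_m1
FEKVLTPSDVGKLNRLVIPKQHAERYFPLDSSNNQKGLLLNFEDRTGKVWRFRYSYWNSSQSYVLTKGWSRFVKEK
>B3_m2
IRKVLTPSAVGKLNNLVIPKQHHESYFPLDSSTNQKGLLLNMEDRTGKVWRFRYSYWNSSQSYVLTKGWSRLVKCK
>B3_m3
FVKVLTPSDVGKLNRLVIPMQHAERYDPLDSSNNRSGLLLNFEDRTTKVWRFRYAYWNSSQSHVLTKPWSRFVKEK
>B3_m4
FEKVLLPSDVGKLNRLVIPKQHAERDFPLDSYNNQKGLLLNFEDRTGKVWRFRYSYWNSSQSIVLTKGWSRRVKEK
>B3_m5
FMKVLTPSDVGKLNRLVIPKKHAERYFPLDSSNNQKGLLLNFEMRTGKVWRFRYSYWNMSQSYVLTKGWSRFVKEK
>B3_m6
FEKVLTPSDVGKLNLLVIPKLHMMRYFPLDSSNNQKGLPLNFEDRTGKVWRFRYSYWNSSQSYVLTAGWMGFVKEK
>B3_m7
FEKVLTPSDVGKLNRLVTPKQHAERYFFTDSSNNQKGLLLNFEDRTGKVWRFSGSFWNSSQSYVLTKGWSRFVKTK
>B3_m8
FNKVLTPSDVNKLNRLVIPKQHAERYFPLDSSRNQKGLLLNFSDRTGKVWRFRYSYWNSSQSYVEKKGWSRFVKEK
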