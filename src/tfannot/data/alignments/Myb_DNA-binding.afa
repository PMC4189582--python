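>Myb_DNA-binding_m1
WTEEEDRLLVEAHKRLGNRWAEIAKRLPGRTDNEIKNHWNTHLKKKL
>Myb_DNA-binding_m2
WTEEEDRLLVEAHKRLGNRWAEIAKKLPGRTDNEIKNHSNTHLKKKL
>Myb_DNA-binding_m3
WTEEEDRLLVEANGQLGNRKAEIAKRLPGRTANEIKNTWNTHLKKKL
>Myb_DNA-binding_m4
WTESEDRLLVEAHKRLGNRWAEIAPRLPGRTDNEIKNHWNTHLKKKL
>Myb_DNA-binding_m5
KTEEEDRGLVEIHKRHGNRWAEIAKRLPGRTDNEIKNHWNTHLKKKL
>Myb_DNA-binding_m6
WTEEEDRLLVEAHKRLGNRWHEWAKRLPGRTDKEIKNHWNTHLTKKQ
>Myb_DNA-binding_m7
WTEEERRLLVEQHKRLGNRWAEIGKRLPGRTDNEIKNHWNTHLFKKL
>Myb_DNA-binding_m8
WTEEEDRLLVEAHKRLWNRWAEYAKRLPGRTDSEIKNHWNTHLKKKL
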