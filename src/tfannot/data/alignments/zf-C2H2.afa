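>zf-C2H2_m1
YKCPECGKSFSRSSHLIRHQRTHTGEKP
>zf-C2H2_m2
YKWPECGKSFSRSLHLIRHQRTHTGETP
>zf-C2H2_m3
YKCPECGKSFSASSHLMRHQRTHTGEKP
>zf-C2H2_m4
YKCPECGKSYSRSSHLDFHKRTPTGEKP
>zf-C2H2_m5
YKCPERGKSFSRSSHLIRHQRTHTGEKP
>zf-C2H2_m6
YKCPETGKSFSRSSHLIRHQRTHTGEKA
>zf-C2H2_m7
YKCPECGKGFSRSSHPIRNQRTHTGEKP
>zf-C2H2_m8
YKCPECGKSFSRSSHLIRHQRIHTGEYC
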