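>Aux_IAA_m1
KLELRLGLPGSEEVVKSSGASKRGFSETVDLKLNLQSNKEGWPPVRSYRKNNLA
>Aux_IAA_m2
KLELRLGLPGSEEVVGSSGATKRGFSETVDSKLNLQHNKEGWPPVRSYRKNNLA
>Aux_IAA_m3
KLEDRLGLPGSEEVVKSSGASKRVFSETVDLQLNLQSNKEGWPEVRSYVKNNLA
>Aux_IAA_m4
KLELRLGLPHSEEVVKSSGASKRGFSETVDLKLNLQSNKEGWPPVRSYRKNNLA
>Aux_IAA_m5
KLELRLGLPGSEEVVKSSGASKRGFSEGVDLKLNLISNKEGWPPVRSYRKNNLA
>Aux_IAA_m6
KLELRMGLPGSEEVVKSSGASKRGFSETVDLKLNLQSNKPGWPPVRSYRKNNLA
>Aux_IAA_m7
KIELRLGLPGSEEYVKSSGASKRGFSETVDLKLNLQSNKEGWPPVRSYRKNLLA
>Aux_IAA_m8
KLELRLGLPGSEEVVKSSGASKRGPSETVDLKLNLQCTKRGWPPDRSYRKNNLA
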