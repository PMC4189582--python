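>RNase_T_m1
DFVAIDTETTGLDPKRDRIIEIGAVKFRGGEIVDEFSTLVNPGRPIPEEATRIHGIT
>RNase_T_m2
DFVAIDTWTTGLDPKRDRIIEIGAVKFRGGEIVDEFSTLVNPGRPIPEEATRIHGIF
>RNase_T_m3
KFVAITTETTWLDPKRDRIIQIGAAKFRGGEIVDEFSELVNPGRPIPEEATRINGIT
>RNase_T_m4
YFVAIDTETTGVDPKNLAIIEIGAVKFRGGEIVDEFITLVNPGRPIPEEATGDHGIE
>RNase_T_m5
DFVAIDTETTGLDPKRDRIIEIGAVNFRGGEIVDEFCTLVNPGRPIPEEATRSHGIT
>RNase_T_m6
DFVAIDYNTTRLQPKRDRIIRTGAVKFRGVEIVDEFSTLVNPGRPIPEEATRIHGIT
>RNase_T_m7
DFVAIDTETTGIDPNRDRIIEILAVKFEGGEIVDEFSTLINPGRPIPEEETRIHGIC
>RNase_T_m8
DFFAIDTEATGLDYKRDRIIEIGAVKFRVGEIVDEFLTLVNPGRPIPEEATRIHGIT
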