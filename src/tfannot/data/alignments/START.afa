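>START_m1
PLEAVRGALAEVEAWERLFDEAGWRVLQESPDGTRVYTRQSPAGSLPLFRGRDFVLLRSW
>START_m2
PLEAVRGALAEVEAWERLFDPFGWRVLQESPDGARVYGRQSPAGSLPLFRGRDFVLLRSW
>START_m3
PLEAVRGALLEVEAWERLFDEAGWRVLQESPDGTRVYTRQSPAGSLPLFRGRDFVLLRDW
>START_m4
PLEAVRGALAEVEAWERLFDEAGWRVLEESPDGTRVYTRESPAGSLPPFRGRDFVLLRSW
>START_m5
PVEAVRGALAEVEAWERLFDEAGWRVYQTSPDGTPVYERQSPAGSLPDFRGRDFVLLRQW
>START_m6
PLEAVRGALAEVEAWERLFDEAGWRVLQESPDGTRVYTSQSPFGSLPLFRGRDFVLLWSW
>START_m7
PLEAVRGALAEVEAWERLFDECQWRVLQESPDGTRVYTRQSPAGSLPLFRGRDFVLLRSW
>START_m8
PLEAVHGALAEVEAWERLFDEAGWRVEQESPDGTRVYVRQSPACSLPLFRDRDPVLLREW
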