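>ITGB1_HUMAN|762|Homo_sapiens
EFAKFEKEKMNAKWDTGENPIYKSAVTTVVNPKYEGK
>ITGB2_HUMAN|734|Homo_sapiens
EYRRFEKEKLKSQWNNDNPLFKSATTTVMNPKFAES
>ITGB3_HUMAN|752|Homo_sapiens
EFAKFEEERARAKWDTANNPLYKEATSTFTNITYRGT
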