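>ITGB5_HUMAN_SYNTH|753|Homo_sapiens
EFAKFQSERSRARYDMASNPLYKEATSTFKNITYRGTFNKSYNGTVD
>ITGB6_HUMAN_SYNTH|748|Homo_sapiens
EYRNFEKEKQNAKWDTGENPLYKSATTTVMNPKYEGSVDFK
>ITGB7_HUMAN_SYNTH|762|Homo_sapiens
EWRKFEKEKMNAKWDTGENPIYKSAVTTVVNPLYKGT
>ITGB8_HUMAN_SYNTH|728|Homo_sapiens
EWRAFQDLKSENGSQRVLEDSSAGTEVSSTRANPGRPEAGSD
>ITGB1_COW_SYNTH|1|Capsaspora_owczarzaki
DRREFANFEKEKSHAKWDTDQNPIYKAATTTFKNPTYAGK
>ITGB2_COW_SYNTH|1|Capsaspora_owczarzaki
DRKEFAEFEKEKANAKWDTGDNPMFKSATTTYKNVTYSGK
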