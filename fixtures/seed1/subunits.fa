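>Hf
INVGSLALEEHGDPQVRVLQVLKSYAIATLTIPNFSSDTTIQKFQDSVIWGAMYTMCDSS
NEFGAGGRGPGTSEDVQAPFGGILPGGRQELVSPYFAINIESNVETPDCTVKLEVDPEGG
AIEPDYEVTLKGAHVINLGLTLEQALSLAMLNNIFQADLHVSTVRELQERKLGFGADGTE
SAVPNGTGYKRIKKSSMFNAVVEADLLGLITGLQGKLADVAAKAALSQESNSMDKCIILS
QLEIGIAASYMNHKMDEGRFSVSDIKQIKVGSIEVKQDEGEDKRDPTMHGEIGLQGSQKT
DGNLNLGTDYNEGYAFGVQVPPSKSYYGIGQES
>Hm
INVGSLALEEHGDPQVRVLQVLKSYAIATLTIPNFSSDTTIQKFQDSVIWGAMYTMCDSS
NEFGAGGRGPGTSEDVQAPFGGILPGGRQELVSPYFAINIESNVETPDCTVKLEVDPEGG
AIEPDYEVTLKGAHVINLGLTLEQALSLAMLNNIFQADLHVSTVRELQERKLGFGADGTE
SAVPNGTGYKRIKKSSMFNAVVEADLLGLITGLQGKLADVAAKAALSQESNSMDKCIILS
QLEIGIAASYMNHKMDEGRFSVSDIKQIKVGSIEVKQDEGEDKRDPTMHGEIGLQGSRKT
DGNLNLGTDYNEGYAFGVQVPPSKSYYGIGQES
>Hs
INVGSLALEEHGDPQVRVLQVLKSYAIATLTIPNFSSDTTIQKFQDSVIWGAMYTMCDSS
NEFGAGGRGPGTSEDVQAPFGGILPGGRQELVSPYFAINIESNVETPDCTVKLEVDPEGG
AIEPDYEVTLKGAHVINLGLTLEQALSLAMLNNIFQADLHVSTVRELQERKLGFGADGTE
SAVPNGTGYKRIKKSSMFNAVVEADLLGLITGLQGKLADVAAKAALSQASNSMDKCIILS
QLEIGIAASYMNHKMDEGRFSVSDIKQIKVGSIEVKQDEGEDKRDPTMHGEIGLQGSRKT
DGNLNLGTDYNEGYAFGVQVPPSKSYYGIGQES
>M
RNLYRLPLRKKISRQSLYPTATQRLMKTGIAGDTGNLKHHEAITIFKARPPVPPKLAFLP
LAGVALDTAIGLDTVAEEGGFGLRSPTHASGFIRVCADVNMLLQQKIFYKGKVFHMMYVA
EAAKASPGGFLKVRPSVRALMRHTSNHAAAKALLRLVGQCTFKGPCENLAPNSGGDKQHA
EGGNLDTAPMKFGYVALGHITDALPIAPAIMLEHGYVLEVPNAGGGIVLMNAIVGVGEKI
IAGGYYYDFQSSYQYLRTEAKQKSERREGLACEKASGHIAIIPGRLFGIDEIDVMKQPVM
ERDRGNNVLPMEPYVIKNKDTARARINVFVV
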