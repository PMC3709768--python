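>Hf
STFVPNHYKHDASPEWRSDANPVGINIMHSESGENDSMFILRMIPKLEHDTCQELSGSAR
INNFGEGGRVYQVFHRYDEDTFGLKGAENLDLEAVSAIVIQLHSWNRMQPSYDLGSEELV
NHVPWWLSMGPQCRVNDTDSVNANMRFLSFNRGEMVEALRNVLSIARSCLTGGKTQCSRL
NENNQRADAMGETTDCLGGLSARTVSKSLIIGQNGCGEFEYILTSLEPEFTKMRRVVSSS
QLKDLIPSLVRRGSEWPGENVGPVSGVVRKRFASEHESRTQRVKRACSDKAALCTSYQFT
DNPKNPQFLAATDRVIKLVEFKNIIRQELKGDE
>Hm
STFVPNHYKHDASPEWRSDANPVGINIMHSESGENDSMFILRMIPKLEHDTCQELSGSAR
INNFGEGGRVYQVFHRYDEDTFGLKGAENLDLEAVSAIVIQLHSWNRMQPSYDLGSEELV
NHVPWWLSMGPQCRVNDTDSVNANMRFLSFNRGEMVEALRNVLSIARSCLTGGKTQCSRL
NENNQRADAMGETTDCLGGLSARTVSKSLIIGQNGCGEFEYILTSLEPEFTKMRRVVSSS
QLKDLIPSLVRRGSEWPGENVGPVSGVVRKRFASEHESRTQRVKRACSDKAALCTSYRFT
DNPKNPQFLAATDRVIKLVEFKNIIRQELKGDE
>Hs
STFVPNHYKHDASPEWRSDANPVGINIMHSESGENDSMFILRMIPKLEHDTCQELSGSAR
INNFGEGGRVYQVFHRYDEDTFGLKGAENLDLEAVSAIVIQLHSWNRMQPSYDLGSEELV
NHVPWWLSMGPQCRVNDTDSVNANMRFLSFNRGEMVEALRNVLSIARSCLTGGKTQCSRL
NENNQRADAMGETTDCLGGLSARTVSKSLIIGQNGCGEFEYILTSLEPAFTKMRRVVSSS
QLKDLIPSLVRRGSEWPGENVGPVSGVVRKRFASEHESRTQRVKRACSDKAALCTSYRFT
DNPKNPQFLAATDRVIKLVEFKNIIRQELKGDE
>M
LKAKVSFNARGLTRLDLEPAKFGSYGAHTSVRAEDDKAMEPQGNYNSLAPWLFSGTDSAK
NSRVGCFDDVRNKVAKKGLFADLVCTSGVLIRDILQNYHGNVQYPRGNTKLIPKQKHGAI
KPIRKDLFSKILAIYPKEVRGAQMGARRQAVAQDDRTAAYTSPKAFDRKISHTQACGGGT
GKPVVSLVGSSEQYGATTGAIKVTKLSRSSKDGPQLLSKENLWEKIDLAKNQGPPGRIYL
KHVPNEFIRKEYAEKLALLLSKVEINKSMAAVARMIAQRSECTCTGIPEGSKNLSNLRLE
QYGNTEGPIWGYMEISAGQLGWKNPILPGVT
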