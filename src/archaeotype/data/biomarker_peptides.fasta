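>M0KI28 Uncharacterized protein | Haloarcula argentinensis ATCC 700875
MVHCPDCETSLETADDIDFVEVDAVTGFIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA
>G0HR47 Uncharacterized protein | Haloarcula hispanica ATCC 33960
MVHCPDCQTSLETADDIEFVEVDAKTGLIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA
>EMA34946 hypothetical protein C444_00145 | Haloarcula japonica ATCC 49778
MVHCPDCQTSLETADDIDFVEVDATTGFIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA
>Q5V7R0 Uncharacterized protein | Haloarcula marismortui ATCC 43049
MPEFRVRKPDGWTTVSFPDEVATISVVGGKVDGQLCLTFTGEREGGTSVVLDRLLPS
>YP_137385 hypothetical protein rrnAC2944 | Haloarcula marismortui ATCC 43049
MVHCPDCETSLETADDIEFVEVDATTGFIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA
>M0JP93 Uncharacterized protein | Haloarcula vallismortis ATCC 29715
MVARLYSATLFALYQLTLLLGIMLLPVAMVTEQFGLRLPMDRAVSGLNEAYDQASA
>M0JI28 Uncharacterized protein | Haloarcula vallismortis ATCC 29715
MVHCPDCETSLETADDIEFVEVDAVTGFIKASKRFYTANCATCGVTIGSGVAGAKSNGGAA
>L0JI54 Uncharacterized protein | Natrinema pellirubrum JCM 10476
MTPEATPVGREADRASDVVGAVDEIDGRPHLVVADIARDDAWIAMAESAAVAVEDHR
>D2RXY3 Uncharacterized protein | Haloterrigena turkmenica DSM 5511
MSTTSPVFCYVCNEEMVLDETLEHHLVYEHKPRELAKQLVAEWEAEELGEAV
>YP_003403049 hypothetical protein Htur_1490 | Haloterrigena turkmenica DSM 5511
MTLEAESVGSVSVTDGDVVAAIDEIGGQPHLVIADIGRDDVWLSMTERDAVSLDEWR
>M0BND2 Uncharacterized protein | Haloterrigena thermotolerans DSM 11552
MTPEATPVGREADRASDVVAAVDEIDGRPHLVVADIARDDAWIAMAESAAVAVEDHR
>Q8PYQ4 50S ribosomal protein L31e | Methanosarcina mazei
MVGKMADDMVKEQIYTIPLREVRKVPAWKRAGRAVKEVRGFLVRHMKTEAEQVKLDKTINECLWEKGCEKPPLSIRVRAVKFADGEVQAELAQ
>D7DR73 50S ribosomal protein L12 | Methanococcus voltaei
MEYIYAALLLNSADKEITEDAVKAVLTAAGIEADDARVKALVAALEGVDIAEAIAKAAAAPVAVAAAAPAAEAPAEEKKEEKKEDTGAAAAAGLGALFG
>D7DV66 50S ribosomal protein L31e | Methanococcus voltaei
MENERIYTIPLRDVTNKVPTTKRAPRAIKKIREYLQKHMKSDNVKLDNSINEKVWERSLNKIPARVRVKAVKQDDVVIATLVE
>D5E990 UPF0235 protein Mmah_0207 | Methanohalophilus mahii DSM 5219
MPIRDAIHTKGNGCIIDFEINPGSSKLVVPSGYNIWRKRVEGKLTESAQKGKANDQLIQRLSHIFQINSSSITIVAGAKTTKKSVHLENVYPKTAEDVLEQYL
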