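>HRAS
MFLWVYWQLTEGGTHTNDFHCIEKWTAIACGDTLALIRIGQWHYWPHANITHYRTTWAYW
QLLLIEKFGKTLVWVLDIGVRYFPAPNPWVKYKFCVYDDA
>KRAS
MQVGHAGQLTGGGSNYKQARYFENFCDCANTPCKTPQNLWIVYYPPPHWNDEQNSFSHKD
QSKDTCFWGCAAPYYACLNDTLNINKQLTQDDQEY
>NRAS
MHVAKKHLVCALLECRHRLNPPDCRQYRDNYYHIENSRCVWCDVKKDRNAGPPENLDPSS
QKPFHTFQIIIQRTIQYPLRGSKRTCDRTF
>TP53
MYEDSVPDWYGGPDKNRAIKYWQKCYTNAQRSGYCDVPFLVSKPSRCQRPKSWHHAKFHI
EEFATKVLNPWRADACYPLNHEEQLHPFWKPIEDKDIRKKWQYKWETGHK
>PTEN
MNNRCAPQYKCTWHDRTDRSKDWFDQRGPERVPDSDGIAPKSYEKDSAKKTGHRDYIDVL
FGQQFKEIPICAIFIRGYRQYLFVE
>GATA3
MPACNKDRRAWAKWENECNVVEQACAVTDYWCCTWGNGDRKHKAVSQACAEGSETTIHVT
TLGFWHKYVS
>BRAF
MLGYEVCSPSSTTTKQHGQQVWLCCFLKHVSPVERHHLRTTTEVYDVYQACSLNQKSPKY
FRHWWSQHLNSNFDQQKTNVYNQYEFREAQRDQRDKGPCEKDGNQWKCATVGQDEPERPW
NNQRFCKSLFNPLCHYKTINHQVNRPAAYTVESGANHKDPLLHKHHHCIFRKALAQVFTE
WLFNVEDGINHHASKISWYWGSLPTKIFHICHHVQFNTFIHAHQCDHLFHADGNSLCCKH
LVPGYYFWTCIYVSFYKPRRALGKEQFRFEHIAYCSVSVNAATVFHFQFVRHGGDKGNRK
VDGPGFPKERGLRKYEYISVAKRPNGQHLKTRRECLTGTWTLRQPIWNDSEFKYCRGSHC
IILFVAVYDVHSLGILTQAAEKNWATEHTPKTYIFSECRVVVCHFNTASCHWSTNSIRFD
GHKGGPTRYEKFREWGIETAGDVRWFNINTTNRGWEVENVEGYYHSQTRKKTQYIPTETR
IRATGFACQFHKEDEAQRRHGPEKFHKCLNDAYEDARYLNISDTWFNIAIFVEQIWSVQK
RCKANAVNWKSSPGEDGSIWACLGHDQYNGREDQEIYRVKKSCVDCYQWGHIQVVEPEVT
HPSAYDIVATRQYCVCVQLGRWPYAIFTKGWVSINGAGEQ
>SMO
MGAIESALCAYFWQRQLACADRVSIGPLCNPPHHQAGLRIYFVLPGWDHQVPGCILPKDW
EGTRHCEATAPQAPGFSRGRYILVHLDVSYDNCDAAIFFVGIDWIAFEGKYPCIQWKKAI
SNTACIRFHETPPLVWLYQEIKYTPIRKRVDQTVCNKSHYGQWSLYNAHPLHQGLQWKVP
NHSVYDWFRAHWEAVSSIFDFKSAQAYENQWDHVGSIEVTGSCFTWCCSIGKEDVEHGLI
RSHHFFWFVIVPWTGFWQLAWEEWINHHRRSEKHVPVWHWPWKVCNCLDYLIKGSSFENK
IHDYPYNQKVFENYRLNNEHVLSEIENCTDTRTWEWIIKDLNIPSLSVELDRVDGCPNEY
WSCDCEVDAEKVCHEDAGSHVHWNTIALYHKCSDNDFYFTNNTHCLNCVRDALNWLPSYT
DNSDSCNVECLLTNFYWDKHSLWLFDQRCHCDATYRYVLYPELWHVSNQHNYDHLTLGHV
SSSKLGFYCFLHCQCCNWFIDNINCEWRKNCVYHRINKASRWRTNVILVFETASWGPFTI
KLFLTECWQCSPTHGYRHEN
>EGFR
MKTHGYESVNTYEFLKKRLHAVGSRSRRGCQKPPSKDCFQRLNEHFQKHSCPGKIVNQHE
DHTAPTWDWCQLGCVHRGINTYYTVNKTQIHGSWQVDDHSRCVTICATAQAWEFGRYRNK
>MYC
MVIVFTPGIKQKPAELHFQAIEWKDDPICWIDSWSVTYKASQEFVEIFWKHYLRHTISRF
AERSPSRWYCFCRHIRIHGRIPTFGWKNCWDTEYGSCWFEHTFRA
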