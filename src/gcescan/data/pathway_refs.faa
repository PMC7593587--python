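>pylB synthetic reference | 3-methylornithine synthase
MWPQVNSTFCHGVWALTDSDLTHHGRGYKLMNNMYTSRPHYLFTEVPDAKADMYLTWTPK
MGLIFYACEYQVFRILAPTQEMGYVEMWTRPARLCFMRMPVQIPNDCQINHFEITKINYI
NKPKPMQYENKIFCKTCKYYFAQAHLVCQMDTTLWPWYNGDNESWFNAEIVYPNNCIYKF
FRAYVNLSMLHKSCARITAWDKYDQRKCMKVQHCNGQVIWMMSSWYEKWHANSRTPDTKT
TYAVPLSYMCRFFEEWIDEIHHWVNYHDGCYFKFYEMYMVVSRNNTKWVIKRWCCFKEMM
YRGSTQQHRDPWYGHPIRFECLFGWTTNDRPWLENLQIHDYSLFPKPCER
>pylC synthetic reference | 3-methylornithine--L-lysine ligase
MCQKASQTVRTDWWQTRVVMTWGAEAKAGGRFWEYNFAHNDEDQCALHNWVMPTKQFPFE
SNIAFTLYWVACNHTHEDHPDSHHQVKSHDTSSVLENNIPGPSCLQCPWTQTIHCRHVLV
DEHALQQFENPWVIEGVLYQNDNITDEQQTMIHIQMGFRFFHVLNCHSSNVGECESWDMD
TDPCRWRGTHSTLPVEAKEVVIHRLCQRCSMTVQHIRCFMWSTEGGRMFRPVNDVECSLP
DRKYPWSTCSPIHPEEVSNSHRFKDIHKLAHTKMDIYMARSIATGWIISDASWYDDHRWT
IWGDKCQYDDEEMNYKWSVELWSFTSDCGLEADHIHKRFLRCWYGVGWQFCIRFMDKAYM
TDEENVPLWEEQVGGMSGTM
>pylD synthetic reference | 3-methylornithyl-N6-L-lysine dehydrogenase
MRPLMYIWSEVIEGDHDMYYWFFQYTFRMKLMWSASHHNYCMFWLVVDSSTYSTRGTRQY
RHHHECSSEIWTNYHTWNEGMGCEYINKTDGNTLRTPTYFKFKAQFTRHLQKFANMSDCR
RSAQYSLLKCRMMWRYCYNKNAWPAWLDPCNSCSNHFAEGVMERLTSWRDNKTELTPATI
QQPKKDNGIERWIKLCSVMCHETTIITCSYKSRVARIVVGNLNTQSQGNIKDEHGPGFKN
YMIHKWIFNSWGVVIHGHVHLWQDCFVFHMLCEYKGTLTELTSQLTIQMHFMHMRTSMCE
RNTLKFCDQNFIPIIGPVGG
>pylS_N synthetic reference | pyrrolysyl-tRNA synthetase N-terminal domain
MLEMVPEFCYHGVHFGICPKYSIRTEEDAHSSILSWGQNPTSISCHFGWKCLCDIKFPLD
TDIEWGVYFAAEKEYLTADLEEAGSSMEKPDKTKLTQEPWFVNQHAAQYP
>pylS_C synthetic reference | pyrrolysyl-tRNA synthetase C-terminal domain
MISWFDYAVDDGHHAVTQWWYIPSQSQINEYVPSHIMGAIRGQNKRVYSCHMCKDNEGHY
KNWAGKVRQIVEKIACSWFCDCSAQSFFGSWSGRRKDHTMDWMHANNETMCEGRSTPWHN
PILRVWGRSWPFREILREQDIDAHYNRFFWRLGVLCVKKIGPHMCTFPGEERCSLLFIRV
WPGCNNMMCIDVVTLTTHCTNKVYVAALMFINSSCIGGTKLYLSYYHKARIAEECCNFYN
NMPSHPNQSSNCTYNKELNSLEEMPVTNDT
>mttB synthetic reference | trimethylamine methyltransferase (Pyl-containing)
MMTRHKKGSIQMKQENDDTTQWPDIFREPTEWRAMHQELLLWWCSEELYMNRLKQDVINY
SSTDKTGHVSGALVMELLPQFMLELDEGYCVFWDPLFIKNRGIAGHTSSGFKKSVKFVMW
IHCRLGKDYKHPSWQDKRTLVDHYEQFDEWYDRCTHAWWAIWIPVCLNWLTNKRTQPYPE
WTIKQSRVCYLGFLHWLWQIKWQKRIFSCLKKFIDKRDECTSANLQITMFOFMGKHMSQI
LHHPSEGDYQESHGLPQARKWNWGQHVPSNSEFRECNYHFRGSFEYNGLPAYLYSATMVP
GRGHNHWAIARNDCRFTHMCMAFWYKWFNRVANFIYQVEPWCVHKATFYADDQPFDGERW
KHMHECQSMQDMQPADYGFNRYRTWPPMFADVHCDDIQTTYSGLPEQAFVHYTFWVYKWH
IMIARKTEFRQMPVVVYHSGVWKMDCEAIYRNRCQMDMQK
>ramA synthetic reference | methylamine methyltransferase corrinoid protein reductive activase
MWYIWFDPEHKQTVPYRVNDFKTKAKQYEHLLYIMGCIKEQHCMGRASMRIVMYGVQWEM
WFYYLRLQVRGNTNGSRPHNPFWNCGTQMLIWITCMGKPCCNQCYKYDVPTTEEYKFPVG
VCPIMPFAMYGNDHDDTWWRDWAGGRDYEVNGKDKQFYQIGSIWLRWYFKRKHPVLISMH
VPQTCVDAYGARHKYNAQEHFWCMLNNDHNDTTMTKNLDEMCPHKVVLITMRDRNFSMRT
GTYMRSKTKVSMETPNRYMIVPLELWGYWTHSQVKPWWWDACYKPKCWLHADMSEMIQHV
PETPWWHQNKATICYKDKVRQGGGSTGHVYCGDISNKFDSMAGQMRRDVNCYNFYALASS
CGVGNMVRSCVLCCRVEGGVHQNKPFWWALEKIVTGMIMWSCQSGRCCLKVTNMCEKKIM
NINDYMHKKGPVVERSLQTDLAYMGCDGTYGHTDPNMTCGSHCLYSVGHEDGVQLLDLLS
FVKCPPWNTFEPLSLSYYCY
>mttC synthetic reference | trimethylamine methyltransferase cognate corrinoid protein
MMIWEITGWNMHDWACCFRCDRAGTWLVVWFGQAGIVYHSMCIRRWPYLRPVWTYIYCIR
PDQISYFNAMTWSGIYSWFITHSDCWHEGASVANIQRRAAWCMLICEMDRVQTPQAMFEV
TDYMPCVWSEMKIMRRFWKRVHVCGRSYKAKSDEKLKMPPKYLQQIPRLLNKSICLWGHF
WDKKNGSTKTDHVPEWVIENNKRQSYSDAY
>cutC synthetic reference | choline trimethylamine-lyase
MTQGSDPIVQHSRGGIMGQMFRCWSCTHQFHAQNCGQSNEPFKLFTRDLDRIIFCDMRPF
WQVACCSIGNQKIIHILHMPQAPHQYIDQHHPPALINPACLTFDIGCWQSVPIADHPQDG
VGDFILLDDFHYGIRHYLISSQDGNIKGGLTIRYDWGCTAYFPFVRYSRWPFFQISPAWY
HGITAEQKKWSDFGQKQFLIEFKQRSENCDLQFETNTCWTTDPMEWTTRERLQNTMGQQG
MQHEHTEILSIYKLVLQIQNYIFDMMCAIAYSCSSRVRMRSNKNIKMREKHEHHYIHIFW
WIDAYTVNPSKTEKDSDMHYKDWNMPYARLDWNWEQAYWVHQETDRQGLLACRQGKSQLV
MALFQDYPSLCKLKFFDLEPFKYMRQVCQFHWIMKDGEKASMCYGHLMQMPHRVDDEHHS
>cutD synthetic reference | choline trimethylamine-lyase activating enzyme
MGVSWYCQVAEGFTDWINKHVIYPIVGHVEVAADPVTPPYWCNIDSMQMCVKFPHQMLCE
VYNLERPMGCYFQCQEQFLKMHHIPTIAEDPTFMLKVGPMVFWVKTPHVADVSGYQFVYS
PVTLSTALWGPLNHPSRTGDMEPIRLNYPWFYFRAQVGEICAKTKGFCIHKHNRAAGFCV
CVCPINMFDVRSPMVEPFQIKHNCSKYKDGLIGHRIEPRLREDSSMLLFRISKTTTGQSR
VEQQIGNGNDIIRAIQLRVSHDCPDTNASEYGNLIECMYHHQYMYQSFNRIRIRLCCWPN
>grdA_like synthetic reference | glycine betaine reductase selenoprotein A homolog
MSGIKQMGMIFEGMIKSQKNAKLGFRAYYPGGMQIKCVWGWTEEKQIREWQGSKSRQDAQ
FCMWRHIQKNTCAVGTGTYWFMAGKAPEEQTYESRTELVNFARCTQGFCHNHLPLFSRLE
LILDLCKQEDGWGWFCSDDMFPMRHGFRIVUQAGPSRTCQMSQQYLVTKQLQKLFPYICR
FQQWNDGGWVKVNHCWVRDNIQVMWEWVTYFEASLGCGYCAGHEFMAYLICEVHQEIHTI
SWHFTWWDPDIKWRWTHVCFVCQVFQNRHDWDHAEQAFHHYEFSLLYFAVGHTPCVWATE
DSNKNFQIHN
>selA synthetic reference | L-seryl-tRNA(Sec) selenium transferase
MQPKINSGVELHWEDQEYSVHRNKLADDSGRRDHGDTIWTVRMKIPKVEILGFNESISCS
LVQTQDYIVMPEVSKKSEGDMIYVNSMKSIHDTSATFVEEGWWQAPGRNVRHSFIFFKVK
DSCNFWLKWLRKNLMKQLPRHECNFISLPDSNALWLIAWFNKMDTEPGQCEWPTISCRDP
LPGDSLDKAVYKHPMSFIFWKPSPAYTHYVNKIGFDEYHFVNAGSGQNADCTRDQEHQVG
FAKNDQPECEEESFMSQKRAPHEEQYDHGLKQDMDTQVRQITIFFMMGNFWAAHWFYHHD
RVTDQKGSPVVVDPLEAFTQSWAKRRQDDKMHQFHDMRYFPCMVCIDMVLRHTFNINGMG
RFHALALVQMFVAECIEEVMRMRSKTDWLEVQMGPTIEESPGLEHTGYQCHHNYGESPIQ
LVWHRMRIHATMIMYTVIQM
>selB synthetic reference | selenocysteine-specific translation elongation factor
MTRMLRMDCYGTDDAFYNASWDNYHHPYWSGLEIYCDCEPISNWHIAWTGFWMWHENVDR
ARVTPMDMWIGVMWAEQSYGGEREWNQGRFECEHDSIAVLQPSAIGNWAYLVYEFSKLHE
TLAWDVRIICIWVYQMTFWMKQNLWITFKGEANGYYHARRISDKFNCFEQKRDRNLIYPV
GNQQKGHWGPQVKGCYKDCMLDVEISKCQIREPVFCLHPVWQWRWYEAAQIRVRKRQCAC
MSTPWGFADMSCTRDHPTTCCLFCLSMNPFQYCQKHDVKIYWCGGYACTRKGAKNPHAGF
YDTRLFCLSHSFGWNMNQNRFTAGHCTLREYAPWVPYKIDQSCMPEMYSYMWYTKMLHNQ
TEMPPCRAPRHHGQFSGTYP
>selD synthetic reference | selenide, water dikinase
MATSQWWKVMAMGRIRGTEFVRAKEVSSFRGPYSSEKNDPGYYMSYCEREIVRLGKDTAD
GIVRVQQFRKETIYVTYGKESIWEYEGYQLIGLFLNGIAVSYQYTEEQFRNYWTLQFWNP
YLVRVDKPGIVVSFVCICGSFLVGWNIPVHICKHNPFHGCGQGKMADASGEEKDPRDYKT
NVNHVVSQDSTPMQQDEGLIQPSFTFFWTDNYQNVNKWWWVGTHINMVENSKVSEERIQS
ARWTLLGLAESHHQMKEHPPIQTCQRRGGKCHVTWAPCWMRFPTKSIFLQFMKVMAAMIC
GHPFTQPRQCPFGSISTFWKEGAEYDVQPVTMNYWHFAKP
>bcct synthetic reference | betaine/carnitine/choline transporter family protein
MQYFLRCGRRFTVKHYGPISPACDYRHWHPLWLCIVIVAPDKMRRFQQAQWMEGSAEEFT
DFVCGFSMENWVWVVYPVHLHDCYQFHPDGCTIFEKQFFVAPAPGHMERVKSSRSYFNYE
HPCGHMNLTNRWNTLKATCVESYNSVTLWDCGYQEIAKPKMECCQAEQSHLLSWTPRTVS
RYICLIAWYLRWLEDCCVRKYMIWRFQYIIMFWFTMQLQVNCRANETPPSFLEPKPPAFF
IYLHTWGLDFMARFMHFKQKRMSLNAEGNYDAPRVLSRAHRINMPWVHLCTAKVWHYDRN
TTKNREPKIGLAPYLLLDMVVYETMGSELMNNCVEYYWGHSNYDNMWCKDSDYHKHHRIC
EDYQWQQRVRLQINDRACFFSRFEHMRGQKCTHQGKQGCTCQNKEVIQTYSQYVANHRDT
YCSLYPWCPSCRTWMITLHWSKATFKAHWGCFEKEEGTGYRCICEAIWYCHQRHLEMFEQ
EALVINEFEFPQHPIHEHHL
>mtbB synthetic reference | dimethylamine methyltransferase
MTWFMDTHPWNWLWQPLYRNETHCVQIMTGWDNRDGSPQQGAVDLVCRCDFIPITCCFAG
PQKHKNTEWIYHSLAAENNEYHCNMDIPKIGIGEFDDGNCKQRLPNYTHCVAIFQATPIA
KNPIDEMFCIFIPEYDYIGRDPMTKFIDSDRINKPSNMQLWCWFYNVADDLASVGGPVCM
FLKICVKWFTVSHQIYTKNWCFFAPQERFVPLLEGHNLPSOTGDHSVSCDHAEGQPTACR
VPQYFRWWGASDCNLRMEVKTPMGCCKLITYCQRKIIKSVCDTDQCKARNIQDPKKCTCH
KRTCFIMDYGTSWWQHNENFPRLSIMFICWIQSNNTECTVAMWKQINHKSTFAYAMMPGD
KYMKAWYCQSCIRVMGQHRAYGDDYWLSFWINIDVSMYCKRHLETGAEVMVMATLDDCMQ
CNVWEGQSQNHWFQWPAEGWHFNKIDDGNA
>mtmB_like synthetic reference | monomethylamine methyltransferase homolog
MRGRQLPHEANMDPFKLYPFHTDRKVKWEFKWVKVQYYTNINTCINSFGISICYIPIRSE
DHCVYDGYNKEIHMQKFLNKVRVGLEWKTCRKVLDSRDDIRSAHWTCRTAIISSNMDQLY
CQMMYTIKHAGGMNYWRPGGLYSKNFCNHHTDPRKQCYWDNWDSLGYLFPNHRDPTSESL
CKGWINPKDYGIHRCFWSNSHTTLRFGPAWSHGAIOVWFAFCRCFVRIDQHRTKDRVLKM
VHHAANYGGGHVWILDFPAMMCLHDPVGNYVSIMCWAAAFVWMMHEPNLRGPTAKADKKA
CCWPHKLCGVEILVWPRPMKIQFFPGLVDFYILRYHLIVWCFPFDVWGPHEVAHCYMTKT
NFAFYSVTPFKFVFTDIKRMTPACKEFDYGQEDWLIEDCQDYGSHPPIFKHHFTITPLRV
DQGQLGIFQFVWFTLVNTWT
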