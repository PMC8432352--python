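>synthetic_vriC synthetic stand-in reference protein (starts with Met)
MCWEGNQWCTNRFYFFFVNVTCRQHWGPMQQTVYMIKHVIVCFHEDYFMCCIIMGGQQKR
QNWFRDGKLRRNTVFHQCVNGMLAGHWHKCPWLCFWAMMCKDKYRAICAPSLNNHFRCRM
VKPNQKRKEYRIMEHSNSESKCRNVWIDFFYGGYGLHWQQGVAPPVWPHTKIMLREFGVV
RMPVAIDEEQCPGNQQDQHHVHARGVCWTQHGSNWTAPWVPAHWPWTMQNQAHLHNRFHH
ADIKLAANSWKRYETFRFYRMSENWETYDYFCVWAAILSTCNGFKCHPFGGTLCALLNCV
VEETSWPFTAHSKAPNFESNEQMNQGNDKR
>synthetic_wedge synthetic stand-in reference protein (starts with Met)
MGVVKLRKMEIKYTDPQMFSDGIQELSQIHSKSVNKCEWPVNPVDYSHHMFMRSLWYGES
QIPGHNIPTWLKQQVRLHATCISHKEVAYITYHLWIRGMMIYETYIKCIFQRLETTSLDV
HKWSEYRTIQNHYGEIHDFLDVFVFQWEPCGSMEQKYSQCALRFYCKWHREQRKGFFCPD
AYSEEYKMKYWVNSTFKDSMSMFRDYPAAYDHLHAFWRMTPYMWFDYYRPDQAQDWLNIP
AFIKASSNYVHFWLACCFKQPLWMSYYVADGQWNHIINYEIYECHAGYELWFAYVIDDYA
SNMPMKAVPL
>synthetic_TSP1 synthetic stand-in reference protein (starts with Met)
MNVHAKQQILEADEKSYEYNQAHECEIAILGPFGKMLSSEATETTCPFTNRRSPAPCDFW
HKTNGTTAVSLSKGNWPVLQTFYKEDGRVITAVNLTEGPMTYKPTNLPPQATNYLWAYCI
WTAEKHLFPHDYGVKPWQSIALYYVSGYSEVWHFCYDHRTIRMDGEMMGPYTNQWFTYVA
NHWWSHSLSIMWDAEIDTCEKLQDMQGTVLELESVACKQNTVEDPSFCWMMAMYYDYCVF
PDQYPGYRGQGHASCRKRGCCCWFNMSLYWAHPEYCDWNDAVIIWQEIRNPYGYDCPPTC
FCHFACAVQMGPPQHTEVFQQKRCKSIHKEKLMVEYVWTLSYMVREMYQELKAIPISHNF
APILDKLHYDPKYKVCPSSHWINFTWTNEEVQYPSFWHEPHMRALEKVLVLHPPDHGLTQ
VYLSIPSTQDFFLFQWPMLGKHVIDTSAVMTNGTCAGHYFPIKVNKCERMVELWYIAMWI
EYWTTSYLKWQMAAIETRTQDCPFGLFPYVRWTWCIDVVSWCPKNEHEYFPKIRTRLEWQ
MIEINTRIRVMYIDQFWAVPSVQYNTRVFHRRWAACLWNYWEEAEWSSCSWYCGNQSHFK
LEMCTMYCLRFGFEFSFRNMCGHMEVTMVGCCLTHSDDNIYFIDSMLNHYDQMACYISFP
VSLFRAPDGFDGQGKYSVVDQWLIMCQPNHNPKDMKIHEKKWIHYLNECVRHGSPEMATW
HSNHNVRPMIMGCLPHFYDLDNQMVCPFRLHVYHSEDYPSQKVIQYPQPP
>synthetic_TSP2 synthetic stand-in reference protein (starts with Met)
MYCEIYWWGCVRTLMRRWMMWVRCTNVDRIHGFICAIFFMDGPALCLQGMLMPDKAWHYG
NVIEDHACAAEIRHEHSCFWKINDHKIFEYPSIYMPEIMRVCRMNEQWWTLICGKRTVKI
IKYGYGQRECDATVTRNGVWTSYDWRGMGKMNMYASADRVIGSQQHNGPYLYWDACFSDG
FNMRCDHSREFLPHELRLLEPLEDGMMAVIMWWRDDMWIWCQLFYHINLTGEALKNGPEP
HSDHGCWSKPCMCCEELKELGFAEVDIKCGIFHLAGARSCEDTALPMRWKHSYTHPCLAE
KILTTCAKTILICMSSGHCPEFLTKDWYEDPHIMMGIMFRPCYMAWLCGKARQVKYIGEE
KVNCITSYDSKIMHEPFWICWRSEICGFDCKGKVMECRELVPKHIYHTCTEIVIIKAFCR
KPYLLRGDCMDPMWHYRQKYYWQALMNNFWQYFSGHDCMIAKLIRGSQVVIETPVVQTHT
FAFRMCLKIYRAYEAGQGFWVTFEWLDEAQMNVYMMMKNKTEVPGPLCRVSLHETKRKVS
SIGDAWIMYMKWRKGQSWCRLFAPYHNYNGNSNKNWKESINQMAALHFMFPKTIRIAGQT
MTFNMKVLSHLYDHDQHKRHQHVQDSEGELFTLQMMYIAADIKAEDCYQGLEDEDQPSLK
YWRHQSCHLTQWPHQREDHMWMTSAYRKVNYHCENPAYHRQSLGEWAHNSWNRIIDHSYG
HNMFLGSDGSNEHQTPQRHFNVLPLAMTKCWWRHRCHKMIPAVQFNSQFQEYRCKHCGGD
QMWHTEMAAHFWCWCFWCFNLKNEHVDNQCAVFMTIFPPHAWWTKMYRICGRYQVFNKSC
NRNYANSSPSSSQFYNAKKKGNLKTEDRRYPYGVMTDLFICIRMYCCNRADVQVQITFGA
HNHVCMMNRGLSVCQTHLIWL
>synthetic_TSP3 synthetic stand-in reference protein (starts with Met)
MWCMWMAMPHNVKHTQSYTFFRAAIAFHYQCDHNSDSDTYKIDHTSAYQTYLHNGLIKIA
GIEMGTTAVSLRDKLMPHTACFYHKLNNFADISSWMSPSLIQFWFLCADRSPKPFISDRP
YGFLSNVDIWPRRPKFMCALEQFVSTLNRDMGYIYCQPFPTQFKHKEHYLEPPRPPKMGE
PPSLQKDQLTEFNHEILGGSNYRPYWQATGDKKCQAANYSNRYRITKHIMTAMGVPWPEW
HLQITMHVQPCEFCWCGPHYCSYLQPMTQTFSQVSNAIYGGGFGNFVLLWRQNYRHNALW
WRHVNVSVAGEDCTSWEYDGFATIMFYVSMYWVEAGQTHWKQCGRDESKKLDVHNFQFEI
HWSKVCNDLDHREYHYNHFHSLKVEALHLMVDDNWTLSDAFWRCFDEGWEKWDITPHCIA
LHVYECKSPELMGWFIQVIDLDLYCWHAWRSLTLNCAALPSRYTRSFKQMMTGTREMRRA
MTVVSPCRCDHCDALYSSLFPMYAIQVETMSVEVYCHISTMPYWIVWIGFTTIFEWWAAH
IEARTEFGELEIKACYNCCVQMKRYHRTWHNTLWICQWHMMLVDIFVDQTMLGGCTVWTA
VRSGRFRKGNQKAHCVTTKPVNNTRGHEMCMWDSCKEMFRAAWWPNNCRFDPVNHWAKTY
VNRVVRRRGQTGDENNIWMLCPTKTLMMDIRVYIWLAI
>synthetic_TSP4 synthetic stand-in reference protein (starts with Met)
MAGAPFLDRHHRQWEECRCRRCIGPWRDPTCQVEWMCNDKEPCLDIVYVSYLGHGTVSII
VNGAPIATTQNYGIELQLTIKWQPRIAEGTHIGRMCRESCMGSWWWWHSVAFITCNTTAQ
VTAFNFRYENRKFHLWNDWDWCIWHDEMQSLNPRRKSKKWSARACENHDWACCVYNDNHY
AQAKKEAAVVIRCVMTAIGTIGIEWSGDYDEWCGGASNACETNFTFNQNWFCVTCKWWDQ
EHIRYEATNSGSVHILGTYKPSAHQQKNICYTPAKHTINWFANWPNSQCYISHGICTWAS
VKSNHIVYLKWLPWVTPFCDLQEPEDMYYCFNFHPAGDLIVDYESIFLCCWCSACVQKDQ
CWIACKWQKMQTAAFFNWVSEWDDNKPIEYGTTAVSLYHLAQCFKRAGQTTQPSIKEKSQ
CCQMATHDFTGMFFGGAFDANYVFSDINQFPARRQHGWKFNQDRHINCHYVVGQAENSRP
SMSGENPWKKWQSAGWATVSFWRGWGQIRHPGESIVKFFGGPNYFSVPRCMNQKLYPLDQ
WCYQESSQMFECTSATQQSSKKPKEGVGSMCCPQYNPHVYNFNKLHFPPHRALQISRAGH
ATPGLSQHCTHETKELLKSGPGCHQREHPHGMKTLKRMRMYTQPTACEDILTMGDSNWTQ
VVTCTNSVDNDVCGMTVGGMRSVEAFRDAKGQWCGAWCHDERTRWLSYPGQKICAPRISG
MHRHHCWGAPIWNTQDYYDRIYFNDTFEQIKPMQCHTWRTKMYPKAGVCITVHSEDIEGP
PIKQQHDPDNMPGQAFDDNIYTLAHMGTIEAWICFNSGTVAKQECFNNPPVRVNKTGWDD
YNKRNDHDLSHRLTAECSFIMQHFRAPFWAWKSHDRCHESHRFMDRLTADWYYDPARCVM
DFKDAIDECSHADCGINEMWGGLTKRECYGTMAGSNFTKCYAQDECRDWYGRNIVFGHAN
QQILACQVTVTVQMPMLTGDIVWILPSCAFWQFFKPTVMKQHPNLQKMILANLHVCARYP
IHDRPYYFTHKQSRVEFSHIMWKNYQGTPTQVGRDQAKISSWNFFQVQMCMVAHEPRPRH
PHEVGVISYTDEAQNKSSENPTMANAMTHKIMCCSQQFMTLLWRAVNVCLPVMHRVWAMY
VHYIMSGCHWHISCMEVNRWTGMDGFP
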