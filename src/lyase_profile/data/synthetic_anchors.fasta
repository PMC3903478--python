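>synthetic-anchor-HAL
YPEPDDHEFNLEPWHCQYYVCGRLRDPSECIEIRNLYNSGFKHLEIPERHEYAETSYIKQ
RRPMRRFPWMVDTAYPHYKFGLSHCWGHHEAFRQWVAGVTFNDWMYMIKVEEYCESNTSL
LKSMECRIGFSMLLMTYWIMWARTVRTPQPCASGREHNLNKEIWYHCHRAFKMHKDKGKD
AKKGFSRSVPWTMNPTVSVCHGVDIESWKPRFPKDKNSTFSMKGMKLNLDCRTQQEIWHC
PTCVTQKSQECGWCNLGHKCCGYHPEHHARQKFDIHPGCLTTQDCGCALEYGPRKSDNSP
>synthetic-anchor-PAL
YGEPDDHEFNIEPYHRQYYVCGRLDDPSECIEFRNLYCSGDWHLEIPTRHFRAETSYIAW
MRPGYRFPYMVRTAYPHYKFGLFLCWGLHEENRQWVAGLTFNDWMAMCKVEEYCESNTSL
LKSMEFRIGFPMLMMRYWIMWARAVRCPQPCASGREHNLVKEIWYHCKRAFCMHKAKGKD
AVKGFSRSVPWTMNPTHSKGHGVDIESWKEKFWQFKNTMFSMKWVCINLDCRTQQIIWHC
PPCVEQKSWECGWCNLEHKCCGYHDEHHARQKKDIHYGFLQTQDCGCALTMRPMKSDTSP
>synthetic-anchor-TAL
YPEPIDCLFNLEPWHRQYRVIGRLPVPSECIEIRNLYYVGFWHLNEPTRHCRAETSYIAW
RRPMYRTPWMVDTAYPHYKFGLHQWWGLHEEPRQWVAGLTFNDWMAMLKVEFYCESNTTL
PKSMLCRIGFSMLMMTYAIMWARTVRCPQPDASGREHNLNKEIWYHTHRALCMHKACGKD
AMKGFSRSVPWTMNPTVNVIHGMDIESWKEKFWQVKNSMFSMKWMCLNLMCRTFQCIWHC
PTCVTQKSQECGWCNLEHKCCGYHDEHHHPQKFDIHPGCLQTQDCGCAGTMRPMKSDVSP
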