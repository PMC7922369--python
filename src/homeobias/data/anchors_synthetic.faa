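>ANCHOR_SNAC_1
MFVKDVMSDELPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
WQDEHNKRYTSMAQFAQCTECKYNTHALPVVTTEGNPFYPDMMFEATVNVSSLAAKFIEC
>ANCHOR_SNAC_2
MVMQEATFELLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
WQDEHNKRYTSMAQFKGKFNKLKFRPQIECMRGAQKDLTKKRVDAQLRDKQNEMIFQSLI
>ANCHOR_ANAC34_1
MFGGLATSVDLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
DYKENWHQRSTFMAPSSRQHDIRLNQWGWIHIWWGINDWNEKDKGECKQMLSGKMGILDW
>ANCHOR_ANAC34_2
MKPRPVYSDSLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
DYKENWHQRSTFMAPSQNPVWYSNYQPDCRGWMWKQAVHCHHDMIISAPPGAAQNNWDAP
>ANCHOR_SND_1
MPRSMHSCADLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
HRQWYDNKESAFTPMVQGARNCKTPLQFPMFDGCCEKQVYHTGVPGMFLSCPPEMPSWMA
>ANCHOR_SND_2
MLHMYNMLPALPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
HRQWYDNKESAFTPMPCWIGGPWRFFPCWCDFGISFNAAMASTMPFVHASGDPFRSPDAL
>ANCHOR_NAC1_1
MEVRDGGERPLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
KWEYHQDNRSPTAMFGIGVFTKNDPYVRYWASNMMWTGSCPFWVVDLFRIPKTQNCTQDH
>ANCHOR_NAC1_2
MWCSPHRCGYLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
KWEYHQDNRSPTAMFGYKHKPDYTKWQQVTATLDCRQVCSHMINSWDSTHQGETPKWWVG
>ANCHOR_NAMCUC3_1
MRKIAPCTQELPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
QHWDKYENRMSFTAPCQPTEVYYEDVYHMKYAEFWRYDQSEKWNVKMARCPAMFPFDEEI
>ANCHOR_NAMCUC3_2
MHDTMMMVRQLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
QHWDKYENRMSFTAPYSCLLLHSMHAEMYPRACACEGWPCKCHGKFIWVNNIEFMWSTNY
>ANCHOR_TIP_1
MPTCRCKQHHLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
EWHKQYDRNTASMPFCPETQNSCKITRVDWAVLGSNVRLKKHKMMMDKEMQHGFRPCSWW
>ANCHOR_TIP_2
MFASVQCTWTLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
EWHKQYDRNTASMPFDCMIYNMEPQAFEILTVVCINLARSVQVEMEIQCTGIAPFSGYYR
>ANCHOR_GROUPII_1
MWLEKFPAHTLPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA
YQWHEDKNRFSPTAMATWWYEPSDNEPAAPVCCHWNNVHQEPPDGFMQAVTMRMWDPGNV
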