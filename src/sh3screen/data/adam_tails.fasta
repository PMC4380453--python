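>ADAM8 cytosolic tail, human
HIIVYRKARSRILSRNVAPKTTMGRSNPLFHQAASRVPAKGGAPAPSRGPQELVPTTHPG
QPARHPASSVALKRPPPAPPVTVSSPPFPVPVYTRQAPKQVIKPTFAPPVPPVKPGAGAA
NPGPAEGAVGPKVALKPPIQRKQGAGAPTAP
>ADAM9 cytosolic tail, human
RDQLWRSYFRKKRSQTYESDGKNQANPSRQPGSVPRHVSPVTPPREVPIYANRFAVPTYA
AKQPQQFPSRPPPPQPKVSSQGNLIPARPAPAPPLYSSLT
>ADAM10 cytosolic tail, human
QICSVHTPSSNPKLPPPKPLPGTLKRRRPPQPIQQPQRQRPRESYQMGHMRR
>ADAM12 cytosolic tail, human
RKTLIRLLFTNKKTTIEKLRCVRPSRPPRGFQPCQAHLGHLGKGLMRKPPDSYPPKDNPR
RLLQCQNVDISRPLNGLNVPQPQSTQRVLPPLHRAPRAPSVPARPLPAKPALRQAQGTCK
PNPPQKPLPADPLARTTRLTHALARTPGQWETGLRLAPLRPAPQYPHQVPRSTHTAYIK
>ADAM15 cytosolic tail, human
MLGASYWYRARLHQRLCQLKGPTCQYRAAQSGPSERPGPPQRALLARGTKQASALSFPAP
PSRPLPPDPVSKRLQAELADRPNPPTRPLPADPVVRSPKSQGPAKPPPPRKPLPADPQGR
CPSGDLPGPGAGIPPLVVPSRPAPPPPTVSSLYL
>ADAM17 cytosolic tail, human
HSILVHCVDKKLDKQYESLSLFHPSNVEMLSSMDSASVRIIKPFPAPQTPGRLQPAPVIP
SAPAAPKLDHQRMDTIQEDPSTDSHMDEDGFEKDPFPNSSTAAKSFEDLTDHPVTRSEKA
ASFKLQRQNRGDSKETEC
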