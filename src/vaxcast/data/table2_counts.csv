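# Per-antigen dose counts from a two-country iDSS diagnostic-accuracy
# field study (6241 immunization visits, 4613 children): doses due per the
# gold standard, doses the iDSS scheduled (yes/no), doses the vaccinator
# administered (yes/no). The Pakistan site's single 14-week IPV dose is
# reported under the label IPV-2, as the study table prints it.
site,label,due_gold,idss_yes,idss_no,vacc_yes,vacc_no
pakistan,BCG,1505,1505,0,1477,28
pakistan,OPV-0,1212,1212,0,1210,2
pakistan,Penta-1,924,923,1,898,26
pakistan,OPV-1,924,923,1,896,28
pakistan,PCV-1,924,923,1,898,26
pakistan,Rota-1,924,923,1,898,26
pakistan,Penta-2,786,785,1,786,0
pakistan,OPV-2,785,784,1,785,0
pakistan,PCV-2,785,784,1,785,0
pakistan,Rota-2,784,783,1,784,0
pakistan,Penta-3,635,634,1,635,0
pakistan,OPV-3,637,636,1,635,2
pakistan,PCV-3,637,636,1,635,2
pakistan,IPV-2,985,982,3,653,332
pakistan,M-1,383,380,3,362,21
pakistan,M-2,209,202,7,208,1
bangladesh,BCG,372,372,0,369,3
bangladesh,Penta-1,425,425,0,419,6
bangladesh,OPV-1,424,424,0,420,4
bangladesh,PCV-1,423,423,0,419,4
bangladesh,IPV-1,425,425,0,420,5
bangladesh,Penta-2,347,347,0,347,0
bangladesh,OPV-2,347,347,0,347,0
bangladesh,PCV-2,346,346,0,346,0
bangladesh,Penta-3,354,354,0,352,2
bangladesh,OPV-3,354,354,0,353,1
bangladesh,PCV-3,354,354,0,353,1
bangladesh,IPV-2,406,406,0,355,51
bangladesh,M-1,144,144,0,137,7
bangladesh,M-2,201,196,5,196,5
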