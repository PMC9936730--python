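# D-genome-standard collinearity order per homoeologous group
# (prose-derived reconstruction; centromere_slot = number of
# short-arm probes).
group	centromere_slot	probes
1	4	1H021,1H059,1H103,1H187,1H236,1H342,1H408,1H431,1H514
2	3	2H045,2H112,2H170,2H288,2H339,2H558,2L-1,2H641
3	3	3H034,3H096,3H151,3H209,3H287,3H335,3H391,3H448
4	4	4H052,4H138,4H289,4H242,4H388,4H435,4H481,4H530,4H604
5	3	5H048,5H116,5H183,5H362,5H470,7H244,5L-1,5H587,5H642
6	4	6H041,6H090,6H125,6H198,6H277,6H356,6H442,6H518,6H590
7	4	7H058,7H109,7H244,7H312,7H401,7H466,7H539,7H611
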