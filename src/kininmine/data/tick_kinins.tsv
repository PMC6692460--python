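name	species	sequence	printed_mass_da
Rmkinin1	Rhipicephalus microplus	QFSPWG	720
Rmkinin2	Rhipicephalus microplus	LHPVDIAVRAADLFSPWG	1963
Rmkinin3	Rhipicephalus microplus	DKDQTFNPWG	1206
Rmkinin4	Rhipicephalus microplus	AGDHFGSWG	932
Rmkinin5	Rhipicephalus microplus	DTFSAWG	782
Rmkinin6	Rhipicephalus microplus	QQDSKNAFSPWG	1363
Rmkinin7	Rhipicephalus microplus	AVRSPTARNDAARAKQEDGEEDEERSFAPWG	3446
Rmkinin8	Rhipicephalus microplus	GTGEDQAFSPWG	1250
Rmkinin9	Rhipicephalus microplus	GDDGDTSFTPWG	1253
Rmkinin10	Rhipicephalus microplus	DDRFNPWG	1005
Rmkinin11	Rhipicephalus microplus	EGPFSPWG	875
Rmkinin12	Rhipicephalus microplus	DGSNKEGFFNPWG	1454
Rmkinin13	Rhipicephalus microplus	GADDPFNPWG	1074
Rmkinin14	Rhipicephalus microplus	QDSFNPWG	949
Rmkinin15	Rhipicephalus microplus	EDGVFRPWG	1061
Rmkinin16	Rhipicephalus microplus	EDNVFRPWG	1118
Rmkinin17	Rhipicephalus microplus	EGNVFGPWG	961
Ixkinin1	Ixodes scapularis	QFSPWG	720
Ixkinin2	Ixodes scapularis	GDKQPEDEAFNPWG	1589
Ixkinin3	Ixodes scapularis	ENDKDKELSFNPWG	1678
Ixkinin4	Ixodes scapularis	GSFSSWG	726
Ixkinin5	Ixodes scapularis	DTFGSWG	768
Ixkinin6	Ixodes scapularis	DTFGPWG	768
Ixkinin7	Ixodes scapularis	DTFGPWG	768
Ixkinin8	Ixodes scapularis	DTFGPWG	768
Ixkinin9	Ixodes scapularis	DTFGPWG	768
Ixkinin10	Ixodes scapularis	DTFGPWG	768
Ixkinin11	Ixodes scapularis	QDKESGFNPWG	1263
Ixkinin12	Ixodes scapularis	DPFNPWG	831
Ixkinin13	Ixodes scapularis	EDKNAFSPWG	1149
Ixkinin14	Ixodes scapularis	DQNFNPWG	976
Ixkinin15	Ixodes scapularis	TTKDSTFSPWG	1225
Ixkinin16	Ixodes scapularis	EGPFNPWG	902
Ixkinin17	Ixodes scapularis	GDSDTAFAPWG	1122
Ixkinin18	Ixodes scapularis	DNNFNPWG	962
Ixkinin19	Ixodes scapularis	DNGNKDSSFSPWG	1409
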