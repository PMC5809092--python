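gene	start	coding_length	g_score
yabB	92438	459	14.48
ftsI	94217	1767	16.07
queA	393434	1071	11.09
ybaL	473629	1677	9.30
mrdA	648900	1902	48.33
nagC	682469	1221	10.57
fabF	1166508	1242	10.50
topA	1329420	2598	52.38
sapF	1350197	807	12.23
pykF	1732965	1413	180.42
infC	1777363	435	14.70
yeeF	2016147	1359	17.65
atoC	2268566	1382	17.55
infB	3248576	2673	43.57
nusA	3251273	1488	9.78
arcB	3285924	2337	14.39
mreC	3326766	1103	27.50
mreB	3327935	1044	46.77
yhdG	3338171	966	11.51
rpsD	3368960	621	13.28
rplF	3373512	534	33.30
malT	3481685	2706	51.73
spoT	3760757	2109	113.18
yicL	3798180	924	11.69
trkH	4011518	1452	25.30
yihP	4044063	1407	10.00
hslU	4099899	1332	93.73
iclR	4201735	825	127.57
plsB	4232975	2424	7.83
hsdM	4559434	1586	9.52
nadR	4615529	1233	106.19
arcA	4627750	717	40.91
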