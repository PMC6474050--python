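peptide	proteins	subject	condition	run	xic_area	charge	n_points
YLYEIAR	P00002	S01	case	S01_case	6.8	2	10
ANCHORPEPTIDEK	P00098;P00099	S01	case	S01_case	393.2	2	10
YLYEIAR	P00002	S01	control	S01_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S01	control	S01_control	390.0	2	10
LVNEVTEFAK	P00001	S02	case	S02_case	15.0	2	10
YLYEIAR	P00002	S02	case	S02_case	11.5	2	10
AEFAEVSK	P00003	S02	case	S02_case	36.4	2	10
ANCHORPEPTIDEK	P00098;P00099	S02	case	S02_case	337.1	2	10
YLYEIAR	P00002	S02	control	S02_control	10.0	2	10
AEFAEVSK	P00003	S02	control	S02_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S02	control	S02_control	380.0	2	10
YLYEIAR	P00002	S03	case	S03_case	3.0	2	10
AEFAEVSK	P00003	S03	case	S03_case	15.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S03	case	S03_case	382.0	2	10
YLYEIAR	P00002	S03	control	S03_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S03	control	S03_control	390.0	2	10
YLYEIAR	P00002	S04	case	S04_case	2.3	2	10
AEFAEVSK	P00003	S04	case	S04_case	10.6	2	10
ANCHORPEPTIDEK	P00098;P00099	S04	case	S04_case	387.1	2	10
YLYEIAR	P00002	S04	control	S04_control	10.0	2	10
AEFAEVSK	P00003	S04	control	S04_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S04	control	S04_control	380.0	2	10
YLYEIAR	P00002	S05	case	S05_case	15.0	2	10
AEFAEVSK	P00003	S05	case	S05_case	15.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S05	case	S05_case	370.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S05	control	S05_control	400.0	2	10
LVNEVTEFAK	P00001	S06	case	S06_case	1.9	2	10
ANCHORPEPTIDEK	P00098;P00099	S06	case	S06_case	398.1	2	10
LVNEVTEFAK	P00001	S06	control	S06_control	10.0	2	10
YLYEIAR	P00002	S06	control	S06_control	15.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S06	control	S06_control	375.0	2	10
LVNEVTEFAK	P00001	S07	case	S07_case	8.6	2	10
YLYEIAR	P00002	S07	case	S07_case	1.8	2	10
AEFAEVSK	P00003	S07	case	S07_case	15.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S07	case	S07_case	374.6	2	10
LVNEVTEFAK	P00001	S07	control	S07_control	10.0	2	10
YLYEIAR	P00002	S07	control	S07_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S07	control	S07_control	380.0	2	10
LVNEVTEFAK	P00001	S08	case	S08_case	13.7	2	10
YLYEIAR	P00002	S08	case	S08_case	1.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S08	case	S08_case	385.3	2	10
LVNEVTEFAK	P00001	S08	control	S08_control	10.0	2	10
YLYEIAR	P00002	S08	control	S08_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S08	control	S08_control	380.0	2	10
LVNEVTEFAK	P00001	S09	case	S09_case	16.3	2	10
YLYEIAR	P00002	S09	case	S09_case	5.7	2	10
AEFAEVSK	P00003	S09	case	S09_case	83.1	2	10
ANCHORPEPTIDEK	P00098;P00099	S09	case	S09_case	294.9	2	10
LVNEVTEFAK	P00001	S09	control	S09_control	10.0	2	10
YLYEIAR	P00002	S09	control	S09_control	10.0	2	10
AEFAEVSK	P00003	S09	control	S09_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S09	control	S09_control	370.0	2	10
YLYEIAR	P00002	S10	case	S10_case	4.2	2	10
ANCHORPEPTIDEK	P00098;P00099	S10	case	S10_case	395.8	2	10
YLYEIAR	P00002	S10	control	S10_control	10.0	2	10
ANCHORPEPTIDEK	P00098;P00099	S10	control	S10_control	390.0	2	10
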