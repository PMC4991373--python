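sample_id	group	sex	age	condition	oct_um	analysis
C1	control	F	54	NA	NA	qPCR
C2	control	F	81	MH	NA	qPCR
C3	control	F	65	MH	NA	qPCR
C4	control	F	76	MH	NA	qPCR
C5	control	F	70	ERM	NA	microarray and qPCR
C6	control	F	46	ERM	NA	qPCR
C7	control	F	84	ERM	NA	qPCR
C8	control	M	78	ERM	NA	qPCR
C9	control	F	63	CAT-MH	NA	microarray
C10	control	F	66	ERM	NA	qPCR
C11	control	F	54	ERM	NA	qPCR
C12	control	F	72	ERM	NA	qPCR
C13	control	M	57	ERM	NA	qPCR
AMD1	case	M	76	NAIVE	401	microarray
AMD2	case	M	86	NAIVE	438	microarray
AMD3	case	F	91	NAIVE	301	qPCR
AMD4	case	M	76	ACTIVE	260	microarray
AMD5	case	F	85	NAIVE	382	qPCR
AMD6	case	F	94	NAIVE	1077	qPCR
AMD7	case	M	63	NAIVE	622	qPCR
AMD8	case	F	96	NAIVE	1150	microarray and qPCR
AMD9	case	F	74	NAIVE	289	qPCR
AMD10	case	F	87	NAIVE	223	qPCR
AMD11	case	F	75	NAIVE	361	qPCR
AMD12	case	F	85	NAIVE	250	qPCR
AMD13	case	F	75	NAIVE	492	qPCR
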