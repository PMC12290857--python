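region	hemisphere	x	y	z
Ventral striatum (VS)	Left	-8	10	0
Ventromedial prefrontal cortex (VMPFC)	Left	-4	44	-8
Ventral striatum (VS)	Right	10	12	-2
Anterior cingulate cortex (ACC)	Right	8	42	10
Frontal pole (FP)	Left	-10	62	18
Subcallosal cingulate cortex (scACC)		2	30	-6
Posterior cingulate cortex (PCC)		-2	-38	28
Anterior insula (AI)	Left	-38	20	-8
Anterior insula (AI)	Right	32	22	-10
Pre-supplementary motor area (preSMA)	Right	4	18	48
Supramarginal gyrus (SMG)	Right	60	-42	28
Supramarginal gyrus (SMG)	Left	-60	-44	36
Middle temporal gyrus (MTG)	Right	54	-30	-6
Superior frontal gyrus (SFG)	Right	24	54	28
Anterior midcingulate cortex (aMCC)		0	24	24
Inferior frontal junction (IFJ)	Right	48	8	26
Middle frontal gyrus (MFG)	Right	40	44	14
Posterior superior temporal sulcus (pSTS)	Right	58	-48	14
Intraparietal sulcus (IPS)	Right	40	-40	46
Posterior middle temporal gyrus (pMTG)	Left	-58	-52	12
Dorsal premotor cortex (dPMC)	Right	38	0	54
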