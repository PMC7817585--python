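patient_id,age,histology_1,grade_1,ptnm_1,stage_1,in_situ_1,ihc_1,interval_months,histology_2,grade_2,ptnm_2,stage_2,in_situ_2,ihc_2,printed_discordance,printed_clinical_call,printed_mtdna_call
C1,46,IC NST,G2,pT1N0M0,1,Yes,Lum,133,ILC,G1,pT1N0M0,1,No,Lum,Histology,bilCBC,NI
C2,59,IC NST,G3,pT1N1M0,2,No,Lum,14,IC NST,G3,pT1N0M1,1,Yes,Lum,InSitu,bilCBC,NI
C3,45,IC NST,G3,pT1N0M0,1,No,Lum-H,69,IC NST,G3,pT2N3M0,3,No,TN,IHC,bilCBC,NI
C4,56,IC NST,G3,pT2N0M0,2,No,Lum,52,ILC,G3,pT1N0M0,1,Yes,Lum-H,Histology/IHC/InSitu,bilCBC,NI
C5,49,ILC,G2,pT1N0M0,1,Yes,Lum,60,IC NST,G2,pT1N0M0,1,No,Lum,Histology,bilCBC,metCBC
C6,54,ILC,G2,pT1N0M0,1,No,Lum,96,IC NST,G3,pT2N0M0,2,Yes,Lum,Histology/InSitu,bilCBC,NI
C7,57,IC NST,G1,pT1N0M0,1,Yes,Lum,44,IC NST,G2,pT1N1M0,2,Yes,Lum,InSitu,bilCBC,NI
C8,79,IC NST,G2,pT1N1M0,2,Yes,Lum,48,IC NST,G2,pT1N1M0,2,No,Lum,None,NI,metCBC
C9,81,IC NST,G3,pT1N1M0,2,No,Lum,87,IC NST,G1,pT1N0M0,1,Yes,Lum,InSitu,bilCBC,metCBC
C10,71,IC NST,G1,pT1N0M0,1,No,Lum,72,IC NST,G1,pT1N0M0,1,No,Lum,None,NI,NI
C11,54,ILC,G1,pT1N0M0,1,No,Lum,0,IC NST,G1,pT1N0M0,1,No,Lum,Histology,bilCBC,NI
C12,57,IC NST,G3,pT3N2M0,3,No,Lum-H,0,IC NST,G2,pT2N0M0,2,Yes,Lum,Stage/IHC,DisNI,NI
C13,64,IC NST,G3,pT1N2M0,3,No,Lum,111,IC NST,G2,pT1N0M0,1,No,Lum,Stage,metCBC,metCBC
C14,72,IC NST,G2,pT2N0M0,2,Yes,Lum,0,ILC,G3,pT1N2M0,3,No,Lum,Stage/Histology,bilCBC,NI
C15,48,IC NST,G3,pT3N2M0,3,No,Lum,0,IC NST,G3,pT2N1M0,3,No,Lum,Stage,metCBC,NI
C16,64,IC NST,G3,pT2N1M0,3,No,Lum-H,73,IC NST,G1,pT1N0M0,1,Yes,Lum,Stage/IHC/InSitu,DisNI,NI
C17,80,IC NST,G2,pT1N1M0,2,Yes,Lum,0,IC NST,G3,pT1N1M0,2,Yes,Lum,InSitu,bilCBC,NI
C18,73,IC NST,G2,pT1N0M0,1,No,Lum,12,IC NST,G2,pT1N0M0,1,No,Her2,IHC,bilCBC,NI
C19,70,IC NST,G2,pT4N3M0,3,No,Lum,0,IC NST,G3,pT1N0M0,1,No,Lum,Stage,metCBC,metCBC
C20,88,IC NST,G1,pT2N0M0,2,No,Lum,14,ILC,G1,pT2N0M0,2,Yes,Lum-H,Histology/IHC/InSitu,bilCBC,NI
C21,32,IC NST,G3,pT4N2M0,3,No,Lum-H,14,IC NST,G3,pT3N2M0,3,No,Lum-H,Stage,metCBC,NI
C22,82,IC NST,G2,pT1N0M0,1,Yes,Lum,96,IC NST,G3,pT2N2M0,3,No,TN,IHC,bilCBC,NI
C23,88,IC NST,G1,pT2N0M0,2,No,Lum,0,IC NST,G1,pT1N0M0,1,No,Lum,None,NI,NI
C24,63,ILC,G3,pT1N0M0,1,No,Lum,13,IC NST,G3,pT1N0M0,1,No,Lum,Histology,bilCBC,NI
C25,43,ILC,G3,pT2N0M0,2,No,Lum,90,IC NST,G2,pT2N0M0,2,No,Lum,Histology,bilCBC,NI
C26,72,IC NST,G2,pT2N0M0,2,No,Lum,0,IC NST,G2,pT1N0M0,1,Yes,Lum,None,NI,NI
C27,78,IC NST,G3,pT2N1M0,3,Yes,TN,0,IC NST,G3,pT1N0M0,1,Yes,TN,Stage/InSitu,DisNI,metCBC
C28,69,IC NST,G2,pT2N0M0,2,No,Lum,0,IC NST,G2,pT1N2M0,3,Yes,Lum,Stage,metCBC,NI
C29,61,IC NST,G3,pT1N1M0,2,No,TN,0,IC NST,G3,pT1N2M0,3,Yes,Lum,Stage/IHC,bilCBC,NI
C30,61,IC NST,G3,pT2N3M0,3,No,Lum,10,IC NST,G2,pT1N1M0,2,No,Lum,Stage,metCBC,metCBC
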