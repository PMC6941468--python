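patient_id,gender,age,implantation,focus_ieeg,surgery_localization,engel,n_seizures,prediction,printed_cdi
FR 115,M,34,right,temporal mesial right,temporal right,Ia,5,right,C
FR 253,F,37,bilateral,(1)temporal mesial left;(2)temporal mesial right,temporal right,Ia,4,right,C
FR 384,F,50,right,frontal right,frontal right,Ia,4,right,C
FR 442,M,21,right,(1)temporal lateral right;(2)temporal mesial right,temporal right,Ia,5,left,D
FR 548,M,17,bilateral,(1)temporal mesial left;(2)temporal lateral left,temporal left,Ia,4,left,C
FR 590,M,18,bilateral,(1)temporal basal left;(2)temporal lateral left;(3)temporal basal right,temporal left,Ia,1,left,C
FR 916,M,23,left,temporal mesial left,temporal left,Ib,5,left,C
FR 958,F,14,left,(1)temporal left;(2)temporal lateral left,none,Ia,1,inconclusive,I
FR 1096,F,32,bilateral,temporal mesial left,temporal left,Ia,5,right,D
FR 1125,F,11,right,temporal mesial right,temporal right,Ia,4,inconclusive,I
FR 273,F,3,left,(1)temporal mesial left;(2)temporal lateral left,temporal left,IIIa,5,right,D
FR 583,F,22,left,temporal lateral left,temporal left,IIa,5,left,C
FR 818,F,27,left,temporal left,temporal left,IIIa,4,inconclusive,I
FR 970,M,15,right,temporal basal right,temporal right,IIa,5,inconclusive,I
FR 1073,F,47,bilateral,(1)temporal mesial right;(2)temporal lateral right,temporal right,IIIa,5,left,D
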