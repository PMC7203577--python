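# Reference amyloidosis cohort: published recovery scores and the blinded
# clinical assessment of each patient's course after treatment.
case,recovery_score,clinical
1,0.71,Recovery
2,0.57,Worsening
3,0.14,Worsening
4,0.57,Stable
5,0.71,Stable
6,0.71,Recovery
7,0.43,Worsening
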