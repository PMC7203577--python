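# Reference amyloidosis cohort (7 patients, baseline and follow-up scans):
# wall-to-cavity volume ratio V_wall/V_LV at early diastole and the
# published scaled end-diastolic pressures (mmHg).  One row per patient.
case,vratio_baseline,vratio_followup,ped_baseline,ped_followup
1,2.2066,2.4505,17.38,15.65
2,1.5379,1.8881,10.91,13.39
3,2.7021,3.8163,19.17,27.07
4,1.9746,1.6576,14.01,11.76
5,2.2003,2.6155,15.57,18.55
6,3.2463,3.1960,23.03,22.67
7,3.5000,5.0283,24.83,35.67
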