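# Reference amyloidosis cohort: published percent changes of the seven
# progression markers, (follow-up - baseline)/baseline x 100, with the
# bootstrap SDs in parentheses reported as *_sd columns, and the shape
# trajectory direction (down = toward the healthy group).
case,vratio_pct,ecc_pct,ecc_sd,ell_pct,ell_sd,work_pct,work_sd,sigma1_pct,sigma1_sd,fslope_pct,fslope_sd,shape_dir
1,11.05,10.66,0.06,-10.72,0.092,-18.86,0.05,-18.20,0.11,-33.86,0.12,down
2,22.77,25.24,0.10,-51.86,0.12,-13.51,0.03,-38.59,0.18,-92.69,0.09,up
3,41.2,-4.77,0.03,65.03,0.16,168.22,0.06,39.79,0.31,428.19,2.26,up
4,-16.05,2.65,0.10,-10.63,0.11,-30.70,0.11,-6.53,0.07,-40.92,0.69,up
5,18.87,70.20,0.18,7.26,0.18,108.82,0.09,-8.50,0.07,-93.09,0.08,down
6,-1.55,-29.86,0.03,0.74,0.06,-14.37,0.04,13.36,0.03,193.59,1.52,down
7,43.67,9.33,0.08,83.90,0.14,154.70,0.15,42.12,0.17,168.10,2.45,down
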