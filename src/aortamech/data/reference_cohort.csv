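patient_id,age_years,sex,height_cm,weight_kg,sbp_mmhg,dbp_mmhg,aad_mm,aad_z_score,viscosity_cp,group
P1,6.9,F,118.0,19.0,108.0,62.0,17.59,0.64,4.28,nondilated
P2,21.8,M,163.0,50.0,130.0,85.0,27.18,1.73,10.01,nondilated
P3,8.7,M,126.0,22.0,107.0,61.0,20.69,1.76,4.08,nondilated
P4,8.4,M,119.0,20.0,98.0,64.0,20.16,1.86,6.73,nondilated
P5,6.1,M,110.0,18.0,105.0,59.0,20.12,2.34,6.48,nondilated
P6,21.3,F,150.0,45.0,105.0,56.0,30.32,3.13,6.07,nondilated
P7,15.2,M,162.0,40.0,112.0,62.0,25.29,3.92,6.08,nondilated
P8,15.1,M,170.0,52.0,95.0,58.0,30.32,4.11,4.14,nondilated
P9,20.3,M,171.0,65.0,140.0,96.0,35.43,4.12,7.18,nondilated
P10,12.0,M,138.0,31.5,88.0,57.0,29.76,4.15,2.78,nondilated
P11,7.6,F,129.0,20.0,79.0,50.0,20.6,5.81,3.82,dilated
P12,7.8,M,113.0,16.0,109.0,74.0,25.7,5.88,7.22,dilated
P13,10.4,F,125.0,23.0,105.0,60.0,30.89,7.03,7.27,dilated
P14,8.8,M,115.0,20.0,105.0,70.0,27.79,7.35,8.83,dilated
P15,19.9,M,166.0,46.0,133.0,77.0,40.17,7.45,8.59,dilated
P16,13.0,M,157.0,37.0,118.0,54.0,35.96,7.82,3.69,dilated
P17,13.2,M,152.0,28.0,129.0,69.0,37.07,8.66,8.3,dilated
P18,19.3,M,170.0,45.0,99.0,63.0,39.26,9.72,7.64,dilated
P19,8.6,F,120.0,15.0,90.0,60.0,28.71,11.36,4.74,dilated
P20,6.9,F,106.0,15.0,99.0,40.0,29.17,11.9,4.1,dilated
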