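table,modality,measure,species,phase,side,aspect,mean_printed,sd_printed,sd_unit
T1,pulse_oximetry,o2sat,rabbit,donor_pre,right,medial,98,0.02,fraction
T1,pulse_oximetry,o2sat,rabbit,donor_pre,right,lateral,98,0.02,fraction
T1,pulse_oximetry,o2sat,rabbit,donor_pre,left,medial,98,0.02,fraction
T1,pulse_oximetry,o2sat,rabbit,donor_pre,left,lateral,96,0.04,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_pre,right,medial,99,0.01,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_pre,right,lateral,98,0.01,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_pre,left,medial,98,0.03,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_pre,left,lateral,98,0.03,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_post,right,medial,91,0.03,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_post,right,lateral,89,0.06,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_post,left,medial,90,0.06,fraction
T1,pulse_oximetry,o2sat,rabbit,recipient_post,left,lateral,90,0.05,fraction
T2,pulse_oximetry,pi,rabbit,donor_pre,right,medial,0.4,0.17,index
T2,pulse_oximetry,pi,rabbit,donor_pre,right,lateral,0.27,0.1,index
T2,pulse_oximetry,pi,rabbit,donor_pre,left,medial,0.34,0.13,index
T2,pulse_oximetry,pi,rabbit,donor_pre,left,lateral,0.34,0.11,index
T2,pulse_oximetry,pi,rabbit,recipient_pre,right,medial,0.37,0.12,index
T2,pulse_oximetry,pi,rabbit,recipient_pre,right,lateral,0.35,0.18,index
T2,pulse_oximetry,pi,rabbit,recipient_pre,left,medial,0.4,0.13,index
T2,pulse_oximetry,pi,rabbit,recipient_pre,left,lateral,0.26,0.08,index
T2,pulse_oximetry,pi,rabbit,recipient_post,right,medial,0.28,0.11,index
T2,pulse_oximetry,pi,rabbit,recipient_post,right,lateral,0.34,0.14,index
T2,pulse_oximetry,pi,rabbit,recipient_post,left,medial,0.3,0.13,index
T2,pulse_oximetry,pi,rabbit,recipient_post,left,lateral,0.27,0.09,index
T3,msi,o2sat,rabbit,donor_pre,right,medial,80,5,percent
T3,msi,o2sat,rabbit,donor_pre,right,lateral,91,2.1,percent
T3,msi,o2sat,rabbit,donor_pre,left,medial,89,1.4,percent
T3,msi,o2sat,rabbit,donor_pre,left,lateral,84,2.8,percent
T3,msi,o2sat,rabbit,recipient_pre,right,medial,86,4.2,percent
T3,msi,o2sat,rabbit,recipient_pre,right,lateral,89,0.7,percent
T3,msi,o2sat,rabbit,recipient_pre,left,medial,91,3.5,percent
T3,msi,o2sat,rabbit,recipient_pre,left,lateral,80,2.1,percent
T3,msi,o2sat,rabbit,recipient_post,right,medial,55,0.21,fraction
T3,msi,o2sat,rabbit,recipient_post,right,lateral,60,0.14,fraction
T3,msi,o2sat,rabbit,recipient_post,left,medial,57,0.19,fraction
T3,msi,o2sat,rabbit,recipient_post,left,lateral,60,0.3,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_pre,right,medial,96,0.02,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_pre,right,lateral,93,0.03,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_pre,left,medial,95,0.01,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_pre,left,lateral,94,0.04,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_post,right,medial,88,0.1,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_post,right,lateral,82,0.05,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_post,left,medial,86,0.08,fraction
T4,pulse_oximetry,o2sat,sheep,ewe_post,left,lateral,85,0.08,fraction
T4,pulse_oximetry,pi,sheep,ewe_pre,right,medial,0.61,0.37,index
T4,pulse_oximetry,pi,sheep,ewe_pre,right,lateral,0.65,0.39,index
T4,pulse_oximetry,pi,sheep,ewe_pre,left,medial,0.68,0.51,index
T4,pulse_oximetry,pi,sheep,ewe_pre,left,lateral,0.72,0.47,index
T4,pulse_oximetry,pi,sheep,ewe_post,right,medial,0.53,0.11,index
T4,pulse_oximetry,pi,sheep,ewe_post,right,lateral,0.71,0.2,index
T4,pulse_oximetry,pi,sheep,ewe_post,left,medial,0.74,0.77,index
T4,pulse_oximetry,pi,sheep,ewe_post,left,lateral,0.64,0.59,index
T5,msi,o2sat,sheep,ewe_pre,right,medial,68,0.1,fraction
T5,msi,o2sat,sheep,ewe_pre,right,lateral,64,0.11,fraction
T5,msi,o2sat,sheep,ewe_pre,left,medial,63,0.13,fraction
T5,msi,o2sat,sheep,ewe_pre,left,lateral,64,0.1,fraction
T5,msi,o2sat,sheep,ewe_post,right,medial,65,0.06,fraction
T5,msi,o2sat,sheep,ewe_post,right,lateral,62,0.08,fraction
T5,msi,o2sat,sheep,ewe_post,left,medial,61,0.05,fraction
T5,msi,o2sat,sheep,ewe_post,left,lateral,62,0.12,fraction
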