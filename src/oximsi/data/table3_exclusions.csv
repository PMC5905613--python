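table,measure,phase,side,aspect,stat,printed,recomputed
T3,o2sat,donor_pre,right,medial,mean,80,84.0
T3,o2sat,donor_pre,right,medial,sd,5,6.3
T3,o2sat,donor_pre,right,lateral,mean,91,85.0
T3,o2sat,donor_pre,right,lateral,sd,2.1,6.4
T3,o2sat,donor_pre,left,medial,mean,89,88.0
T3,o2sat,donor_pre,left,medial,sd,1.4,4.6
T3,o2sat,donor_pre,left,lateral,sd,2.8,1.5
T3,o2sat,recipient_pre,right,medial,sd,4.2,2.8
T3,o2sat,recipient_pre,right,lateral,mean,89,81.0
T3,o2sat,recipient_pre,right,lateral,sd,0.7,9.0
T3,o2sat,recipient_pre,left,medial,mean,91,82.0
T3,o2sat,recipient_pre,left,medial,sd,3.5,15.0
T3,o2sat,recipient_pre,left,lateral,mean,80,74.0
T3,o2sat,recipient_pre,left,lateral,sd,2.1,7.9
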