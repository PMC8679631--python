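# Imaging features of the 26 HCC lesions (16 patients), transcribed verbatim.
# Columns: patient_id; lesion_location; size_mm; visual_uptake category
# (hyperintense|isotense|hypotense|mixed|rim); background liver SUV_mean;
# baseline SUV60_mean / SUV60_max; mRECIST category (CR|PR|SD|PD|NE);
# percentage change in SUV60_mean / SUV60_max after TACE (NE = not evaluable);
# progression-free survival in months (first lesion per patient only);
# flag records per-lesion footnotes.
patient_id,lesion_location,size_mm,visual_uptake,background_suv_mean,suv60_mean_pre,suv60_max_pre,mrecist,pct_change_mean,pct_change_max,pfs_months,flag
1,"Diffuse disease, R lobe",117,isotense,4.3,3.4,5.1,PR,-12.2,13.9,3,
2,Segment V/VI,56,rim,4.9,4.3,7.8,PR,-55.5,-45.5,6.6,
3,Segment VII,60,isotense,6.3,5.7,7.9,SD,-65.2,-42.6,5.3,
4,Segment VI,20,isotense,5.5,2.8,5.5,SD,-6.0,-14.4,4.5,
4,Segment V,52,isotense,5.5,4.1,5.8,SD,-0.9,-6.7,,
5,Segment II,44,hyperintense,6.6,7.5,10.3,SD,-37.4,1.4,11.4,
5,Segment VI,24,hyperintense,6.6,7.6,9.9,SD,10.9,-0.7,,untreated
5,Segment IV,19,hyperintense,6.6,7.3,9.8,SD,15.5,26.2,,
5,Segment IV,16,hyperintense,6.6,7.8,10.3,SD,5.9,1.9,,
5,Segment VIII,15,hyperintense,6.6,7.1,9.4,SD,0.07,0.9,,
5,Segment IV,13,hyperintense,6.6,7.8,11.3,SD,-4.7,0.9,,
5,Segment VIII,19,hyperintense,6.6,7.1,8.2,PR,22.2,36.5,,
6,Segment III,22,hyperintense,4.8,7.6,10.2,NE,-69.2,-61.9,17.3,
7,Segment III,22,hyperintense,6.1,10.9,14.3,NE,NE,NE,8.0,
8,Segment VIII,42,hyperintense,6.5,7.8,11.5,PR,-66.4,-41.5,1.5,
9,Segment II,28,hyperintense,6.3,7.9,10.3,CR,-58.6,-46.1,5.2,
10,Segment I,62,hyperintense,7.7,8.1,20.4,PR,-71.3,-41.0,1.1,died_unrelated
11,Segment III,38,hyperintense,6.1,7.1,10.6,PR,-29.0,-21.5,7.8,
12,Segment VIII,59,mixed,8.0,5.1,10.9,PR,-55.8,-32.8,16.7,
12,Segment IV,60,hypotense,8.0,2.9,8.4,PR,-51.6,-33.9,,photopenic
13,Segment VI,31,hyperintense,4.8,6.4,8.9,CR,-39.4,-48.6,19.1,
14,Segment VII (sagittal),18,hyperintense,5.3,5.3,7.4,CR,-33.9,-30.5,8.1,
14,Segment VIII,26,hyperintense,5.3,6.3,7.5,CR,-33.5,-39.1,,
14,Segment VII (medial),10,hyperintense,5.3,6.6,8.0,SD,17.2,30.9,,
15,Segment VIII,34,hyperintense,5.5,7.3,10.4,PR,-52.4,-46.3,8.9,
16,Segment VI/VII,73,hyperintense,5.7,6.6,11.6,PR,-65.8,-24.1,14.5,transplant
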