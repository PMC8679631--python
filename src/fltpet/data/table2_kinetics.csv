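# Baseline dynamic PET kinetic parameters of the 14 modeled subjects,
# transcribed verbatim.  K1 in mL/min/g; k2, k3, k4 in 1/min; vb as printed
# (two entries are typographically odd: patient 1's "5.0E-0" is >= 1 and is
# loaded with a quality flag; patient 18 has no lesion-table counterpart).
# ki_printed is the published net influx constant in mL/min/g.
patient_id,K1,k2,k3,k4,vb,ki_printed,flag
1,0.16,0.10,0.10,0.11,5.0E-0,0.08,vb_out_of_range
2,0.17,0.076,0.074,0.07,0.015,0.09,
3,0.31,0.40,0.24,0.04,0.019,0.11,
4,0.21,0.28,0.13,0.06,0.034,0.07,
5,0.34,0.17,0.097,0.04,0.03,0.13,
6,0.43,0.28,0.086,0.01,0.058,0.10,
8,0.282,0.28,0.13,0.02,0.04,0.09,
9,0.29,0.53,0.32,0.04,0.05,0.11,
11,0.41,0.51,0.17,0.02,0.07,0.10,
13,0.11,0.16,0.04,0.001,0.10,0.02,
14,0.46,0.42,0.13,0.03,2.9E-04,0.11,
15,0.58,0.69,0.13,0.02,0.07,0.09,
16,0.26,0.18,0.08,0.02,0.07,0.08,
18,0.23,0.19,0.09,0.02,8.0E-06,0.07,no_lesion_record
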