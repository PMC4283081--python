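# Mean-scenario GMS claims rate (number of claimants / GMS population) by region,
# gender and age cohort, Ireland 2007. Values transcribed from the source table.
# "total" column and the TOTAL row are the printed claimant-weighted marginals,
# transcribed as printed, never recomputed.
region,gender,0-11,12-15,16-24,25-34,35-44,45-54,55-64,65-69,70-74,75+,total
Eastern,male,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
Eastern,female,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
Midland,male,1.00,0.99,0.99,0.99,1.00,1.00,1.00,1.00,1.00,1.00,1.00
Midland,female,1.00,0.99,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
Mid-Western,male,0.93,0.88,0.90,0.91,0.91,0.94,0.96,0.90,0.97,0.99,0.93
Mid-Western,female,0.93,0.88,0.93,0.93,0.93,0.95,0.96,0.98,0.98,0.98,0.95
North-Eastern,male,0.88,0.82,0.85,0.86,0.87,0.91,0.93,0.95,0.94,0.95,0.90
North-Eastern,female,0.88,0.82,0.91,0.90,0.90,0.92,0.95,0.94,0.96,0.95,0.91
North-Western,male,0.87,0.81,0.83,0.83,0.84,0.88,0.91,0.93,0.95,0.94,0.88
North-Western,female,0.85,0.81,0.87,0.88,0.88,0.90,0.92,0.94,0.95,0.94,0.90
South-Eastern,male,0.96,0.94,0.94,0.95,0.96,0.97,0.98,0.98,0.98,0.99,0.96
South-Eastern,female,0.97,0.94,0.96,0.97,0.97,0.97,0.98,0.99,0.99,0.99,0.97
Southern,male,0.97,0.95,0.96,0.96,0.97,0.98,0.98,0.99,0.99,0.99,0.97
Southern,female,0.97,0.95,0.97,0.97,0.98,0.98,0.99,0.99,0.99,0.99,0.98
Western,male,0.87,0.81,0.83,0.85,0.87,0.89,0.92,0.93,0.94,0.95,0.88
Western,female,0.87,0.81,0.89,0.88,0.89,0.91,0.93,0.94,0.95,0.95,0.90
TOTAL,all,0.93,0.90,0.93,0.93,0.93,0.95,0.96,0.97,0.97,0.98,0.95
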