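# Mean-scenario average pharmacy cost per claim (EUR per claimant) by region,
# gender and age cohort, Ireland 2007. Values transcribed from the source table.
# "total" column and the TOTAL row are the printed claimant-weighted marginals,
# transcribed as printed, never recomputed.
# Transcription corrections (typography only):
#   North-Eastern female 12-15: printed "438.25'" -> 438.25 (stray prime mark)
#   Southern male 0-11: printed "310. 32" -> 310.32 (stray space)
#   Region header printed "Midlands" here, "Midland" elsewhere -> "Midland"
region,gender,0-11,12-15,16-24,25-34,35-44,45-54,55-64,65-69,70-74,75+,total
Eastern,male,228.09,352.31,468.36,663.13,715.28,1024.07,1225.56,1301.78,1111.03,1261.80,835.14
Eastern,female,250.13,314.96,370.39,434.52,622.62,1036.64,1182.49,1339.82,1233.99,1565.85,835.14
Midland,male,252.32,346.52,570.72,862.57,843.18,1053.12,1212.19,1306.25,1374.38,1483.05,930.43
Midland,female,286.53,287.65,433.68,527.21,784.65,1039.87,1280.93,1344.24,1510.02,1809.51,930.43
Mid-Western,male,312.55,518.26,632.72,780.04,943.63,946.39,1122.24,1150.38,1145.96,1224.23,877.64
Mid-Western,female,331.60,391.68,381.46,574.27,779.34,1001.62,1261.18,1233.93,1298.71,1522.60,877.64
North-Eastern,male,287.17,387.18,546.40,807.66,811.09,919.99,1136.46,1141.29,1192.14,1363.01,859.24
North-Eastern,female,290.24,438.25,324.13,502.04,671.81,970.68,1129.80,1329.20,1337.70,1598.56,859.24
North-Western,male,224.88,313.54,411.39,607.13,721.31,792.40,909.40,976.33,958.41,1216.81,713.16
North-Western,female,257.50,264.09,294.35,388.02,566.78,767.27,1016.47,1076.26,1102.82,1398.05,716.16
South-Eastern,male,272.48,397.70,591.81,817.17,846.95,1009.93,1087.12,1150.66,1200.19,1286.47,866.05
South-Eastern,female,247.29,389.64,380.57,454.17,753.83,1114.55,1223.04,1277.73,1314.70,1504.99,866.05
Southern,male,310.32,407.65,617.11,884.82,891.47,1039.17,1228.63,1315.09,1223.99,1265.83,918.41
Southern,female,357.49,454.20,416.13,583.39,754.74,1132.37,1240.35,1375.76,1380.47,1489.19,918.41
Western,male,298.90,375.46,555.50,865.61,822.04,935.52,1069.00,1199.25,1124.97,1307.75,855.40
Western,female,321.00,322.29,339.24,563.25,744.94,1035.37,1123.41,1238.10,1330.83,1535.57,855.40
TOTAL,all,283.03,372.59,458.37,644.69,767.10,988.69,1153.02,1234.75,1240.02,1427.08,856.14
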