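# Synthetic molar extinction coefficients of human hemoglobin (cm^-1 M^-1).
# Anchor points transcribed from the standard compiled whole-blood
# tabulation (W.B. Gratzer / N. Kollias compilation, as distributed by the
# Oregon Medical Laser Center), PCHIP-interpolated to a 2-nm grid.
# Values are approximate stand-ins for the compilation, adequate for
# simulation and unmixing tests; not for quantitative absolute dosimetry.
wavelength_nm,eps_hbo2,eps_hb
650,368.00,3750.00
652,356.54,3637.98
654,345.85,3529.46
656,336.09,3424.66
658,327.42,3323.77
660,320.00,3227.00
662,313.61,3134.59
664,307.89,3046.05
666,302.77,2960.51
668,298.16,2877.12
670,294.00,2795.00
672,289.91,2714.18
674,285.86,2635.15
676,282.24,2557.72
678,279.49,2481.73
680,278.00,2407.00
682,277.34,2332.18
684,276.78,2257.34
686,276.36,2184.40
688,276.09,2115.31
690,276.00,2052.00
692,276.89,1995.11
694,279.23,1942.73
696,282.53,1892.99
698,286.28,1844.04
700,290.00,1794.00
702,293.93,1742.21
704,298.51,1689.92
706,303.53,1638.11
708,308.76,1587.81
710,314.00,1540.00
712,319.09,1495.37
714,324.18,1453.10
716,329.53,1411.94
718,335.39,1370.66
720,342.00,1328.00
722,349.87,1276.49
724,359.03,1216.94
726,369.06,1160.55
728,379.52,1118.50
730,390.00,1102.00
732,400.42,1102.60
734,411.11,1104.36
736,422.18,1107.23
738,433.77,1111.13
740,446.00,1116.00
742,459.23,1139.38
744,473.44,1191.30
746,488.23,1260.43
748,503.22,1335.44
750,518.00,1405.00
752,532.96,1486.18
754,548.00,1570.87
756,562.00,1610.00
758,574.20,1588.09
760,586.00,1548.00
762,598.57,1507.76
764,611.46,1461.46
766,624.47,1411.68
768,637.39,1361.00
770,650.00,1312.00
772,662.89,1263.44
774,676.20,1213.59
776,689.07,1164.33
778,700.62,1117.51
780,710.00,1075.00
782,716.86,1036.75
784,722.19,1001.10
786,727.09,967.46
788,732.65,935.29
790,740.00,904.00
792,751.53,871.56
794,767.30,838.23
796,784.91,806.93
798,801.94,780.55
800,816.00,762.00
802,826.93,749.55
804,836.58,739.24
806,845.56,730.66
808,854.50,723.39
810,864.00,717.00
812,874.04,710.77
814,884.23,704.70
816,894.59,699.45
818,905.17,695.66
820,916.00,694.00
822,927.37,693.68
824,939.27,693.47
826,951.28,693.31
828,963.00,693.17
830,974.00,693.00
832,984.40,692.80
834,994.51,692.60
836,1004.22,692.40
838,1013.42,692.20
840,1022.00,692.00
842,1029.98,691.77
844,1037.51,691.50
846,1044.65,691.26
848,1051.46,691.07
850,1058.00,691.00
852,1064.34,691.29
854,1070.48,692.08
856,1076.35,693.22
858,1081.88,694.57
860,1087.00,696.00
862,1091.65,697.64
864,1095.88,699.70
866,1099.80,702.14
868,1103.52,704.90
870,1107.16,707.95
872,1110.82,711.25
874,1114.63,714.75
876,1118.68,718.40
878,1123.10,722.16
880,1128.00,726.00
882,1133.74,730.25
884,1140.43,735.17
886,1147.84,740.61
888,1155.69,746.42
890,1163.74,752.42
892,1171.73,758.47
894,1179.41,764.42
896,1186.52,770.09
898,1192.80,775.34
900,1198.00,780.00
902,1202.63,784.12
904,1207.27,787.89
906,1211.83,791.40
908,1216.20,794.75
910,1220.25,798.00
912,1223.88,801.25
914,1226.98,804.60
916,1229.45,808.11
918,1231.15,811.88
920,1232.00,816.00
922,1232.36,820.50
924,1232.69,825.32
926,1232.99,830.41
928,1233.25,835.74
930,1233.47,841.25
932,1233.66,846.91
934,1233.81,852.65
936,1233.91,858.45
938,1233.98,864.25
940,1234.00,870.00
942,1232.96,875.82
944,1230.31,881.80
946,1226.79,887.86
948,1223.11,893.95
950,1220.00,900.00
952,1217.62,905.93
954,1215.47,911.80
956,1213.32,917.71
958,1210.91,923.74
960,1208.00,930.00
962,1204.23,936.57
964,1199.53,943.41
966,1194.08,950.47
968,1188.07,957.66
970,1181.66,964.93
972,1175.03,972.21
974,1168.38,979.42
976,1161.87,986.50
978,1155.68,993.38
980,1150.00,1000.00
982,1144.66,1006.42
984,1139.40,1012.75
986,1134.20,1018.99
988,1129.08,1025.14
990,1124.04,1031.20
992,1119.07,1037.16
994,1114.18,1043.03
996,1109.37,1048.79
998,1104.64,1054.45
1000,1100.00,1060.00
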