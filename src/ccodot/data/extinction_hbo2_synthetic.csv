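# units: mM^-1 cm^-1
# chromophore: HbO2
# SYNTHETIC stand-in table: smooth monotone-cubic curve anchored to widely cited literature values; not a digitization of any single published compendium.
wavelength_nm,value
700,0.2900
702,0.2937
704,0.2979
706,0.3026
708,0.3077
710,0.3133
712,0.3192
714,0.3255
716,0.3321
718,0.3389
720,0.3460
722,0.3536
724,0.3619
726,0.3708
728,0.3803
730,0.3904
732,0.4009
734,0.4118
736,0.4230
738,0.4344
740,0.4460
742,0.4582
744,0.4713
746,0.4851
748,0.4995
750,0.5141
752,0.5290
754,0.5438
756,0.5583
758,0.5725
760,0.5860
762,0.5991
764,0.6121
766,0.6249
768,0.6376
770,0.6502
772,0.6625
774,0.6747
776,0.6867
778,0.6985
780,0.7100
782,0.7213
784,0.7324
786,0.7432
788,0.7539
790,0.7644
792,0.7748
794,0.7852
796,0.7955
798,0.8057
800,0.8160
802,0.8262
804,0.8363
806,0.8462
808,0.8561
810,0.8660
812,0.8759
814,0.8858
816,0.8957
818,0.9058
820,0.9160
822,0.9265
824,0.9375
826,0.9487
828,0.9600
830,0.9713
832,0.9824
834,0.9932
836,1.0035
838,1.0131
840,1.0220
842,1.0302
844,1.0380
846,1.0454
848,1.0525
850,1.0593
852,1.0660
854,1.0725
856,1.0790
858,1.0855
860,1.0920
862,1.0986
864,1.1052
866,1.1118
868,1.1184
870,1.1248
872,1.1311
874,1.1372
876,1.1431
878,1.1487
880,1.1540
882,1.1589
884,1.1635
886,1.1678
888,1.1720
890,1.1760
892,1.1800
894,1.1842
896,1.1885
898,1.1931
900,1.1980
902,1.2039
904,1.2110
906,1.2190
908,1.2272
910,1.2354
912,1.2431
914,1.2499
916,1.2552
918,1.2587
920,1.2600
922,1.2597
924,1.2588
926,1.2574
928,1.2555
930,1.2533
932,1.2509
934,1.2482
936,1.2455
938,1.2427
940,1.2400
942,1.2371
944,1.2337
946,1.2300
948,1.2259
950,1.2217
952,1.2173
954,1.2128
956,1.2084
958,1.2041
960,1.2000
962,1.1961
964,1.1923
966,1.1885
968,1.1848
970,1.1810
972,1.1772
974,1.1732
976,1.1690
978,1.1646
980,1.1600
982,1.1551
984,1.1499
986,1.1444
988,1.1387
990,1.1327
992,1.1266
994,1.1202
996,1.1137
998,1.1069
1000,1.1000
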