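# units: mM^-1 cm^-1
# chromophore: HHb
# SYNTHETIC stand-in table: smooth monotone-cubic curve anchored to widely cited literature values; not a digitization of any single published compendium.
wavelength_nm,value
700,1.7940
702,1.7317
704,1.6714
706,1.6136
708,1.5586
710,1.5069
712,1.4587
714,1.4145
716,1.3748
718,1.3398
720,1.3100
722,1.2828
724,1.2558
726,1.2296
728,1.2048
730,1.1821
732,1.1622
734,1.1455
736,1.1329
738,1.1248
740,1.1220
742,1.1347
744,1.1671
746,1.2110
748,1.2581
750,1.3000
752,1.3440
754,1.3933
756,1.4334
758,1.4500
760,1.4406
762,1.4158
764,1.3805
766,1.3394
768,1.2976
770,1.2600
772,1.2251
774,1.1888
776,1.1517
778,1.1145
780,1.0780
782,1.0414
784,1.0044
786,0.9679
788,0.9327
790,0.9000
792,0.8674
794,0.8342
796,0.8034
798,0.7780
800,0.7610
802,0.7497
804,0.7391
806,0.7294
808,0.7207
810,0.7131
812,0.7065
814,0.7012
816,0.6971
818,0.6943
820,0.6930
822,0.6925
824,0.6920
826,0.6915
828,0.6911
830,0.6908
832,0.6905
834,0.6903
836,0.6901
838,0.6900
840,0.6900
842,0.6907
844,0.6926
846,0.6955
848,0.6991
850,0.7031
852,0.7073
854,0.7113
856,0.7150
858,0.7179
860,0.7200
862,0.7214
864,0.7225
866,0.7235
868,0.7244
870,0.7252
872,0.7260
874,0.7268
876,0.7277
878,0.7288
880,0.7300
882,0.7316
884,0.7338
886,0.7363
888,0.7390
890,0.7417
892,0.7442
894,0.7465
896,0.7483
898,0.7496
900,0.7500
902,0.7499
904,0.7498
906,0.7495
908,0.7492
910,0.7487
912,0.7483
914,0.7477
916,0.7472
918,0.7466
920,0.7460
922,0.7454
924,0.7448
926,0.7443
928,0.7437
930,0.7432
932,0.7428
934,0.7425
936,0.7422
938,0.7421
940,0.7420
942,0.7421
944,0.7423
946,0.7427
948,0.7433
950,0.7440
952,0.7448
954,0.7458
956,0.7470
958,0.7482
960,0.7496
962,0.7512
964,0.7528
966,0.7546
968,0.7565
970,0.7585
972,0.7606
974,0.7629
976,0.7652
978,0.7676
980,0.7701
982,0.7728
984,0.7755
986,0.7783
988,0.7812
990,0.7841
992,0.7872
994,0.7903
996,0.7935
998,0.7967
1000,0.8000
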