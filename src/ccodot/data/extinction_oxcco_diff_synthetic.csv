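# units: mM^-1 cm^-1
# chromophore: oxCCO (oxidized-minus-reduced difference spectrum)
# SYNTHETIC stand-in table: smooth monotone-cubic curve anchored to widely cited literature values; not a digitization of any single published compendium.
wavelength_nm,value
700,1.4000
702,1.4452
704,1.4915
706,1.5391
708,1.5879
710,1.6378
712,1.6888
714,1.7408
716,1.7939
718,1.8480
720,1.9031
722,1.9591
724,2.0160
726,2.0738
728,2.1324
730,2.1919
732,2.2521
734,2.3130
736,2.3747
738,2.4370
740,2.5000
742,2.5650
744,2.6333
746,2.7042
748,2.7775
750,2.8525
752,2.9289
754,3.0061
756,3.0838
758,3.1614
760,3.2385
762,3.3146
764,3.3893
766,3.4620
768,3.5324
770,3.6000
772,3.6660
774,3.7319
776,3.7976
778,3.8628
780,3.9274
782,3.9911
784,4.0540
786,4.1156
788,4.1759
790,4.2347
792,4.2919
794,4.3471
796,4.4004
798,4.4514
800,4.5000
802,4.5473
804,4.5940
806,4.6398
808,4.6843
810,4.7271
812,4.7676
814,4.8056
816,4.8406
818,4.8722
820,4.9000
822,4.9269
824,4.9537
826,4.9771
828,4.9937
830,5.0000
832,4.9971
834,4.9894
836,4.9781
838,4.9646
840,4.9500
842,4.9320
844,4.9080
846,4.8788
848,4.8452
850,4.8082
852,4.7684
854,4.7269
856,4.6844
858,4.6418
860,4.6000
862,4.5571
864,4.5113
866,4.4630
868,4.4127
870,4.3610
872,4.3085
874,4.2556
876,4.2028
878,4.1508
880,4.1000
882,4.0500
884,4.0000
886,3.9500
888,3.9000
890,3.8500
892,3.8000
894,3.7500
896,3.7000
898,3.6500
900,3.6000
902,3.5498
904,3.4991
906,3.4480
908,3.3967
910,3.3451
912,3.2934
914,3.2417
916,3.1900
918,3.1384
920,3.0869
922,3.0358
924,2.9850
926,2.9346
928,2.8846
930,2.8353
932,2.7866
934,2.7387
936,2.6915
938,2.6453
940,2.6000
942,2.5553
944,2.5109
946,2.4668
948,2.4229
950,2.3792
952,2.3359
954,2.2928
956,2.2501
958,2.2076
960,2.1654
962,2.1236
964,2.0821
966,2.0409
968,2.0001
970,1.9596
972,1.9195
974,1.8797
976,1.8403
978,1.8013
980,1.7627
982,1.7245
984,1.6867
986,1.6493
988,1.6124
990,1.5758
992,1.5398
994,1.5041
996,1.4690
998,1.4342
1000,1.4000
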