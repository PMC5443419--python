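# units: dimensionless
# quantity: DPF, adult head
# SYNTHETIC stand-in table: smooth monotone-cubic curve anchored to widely cited literature values; not a digitization of any single published compendium.
wavelength_nm,value
700,6.6000
702,6.5888
704,6.5777
706,6.5667
708,6.5559
710,6.5451
712,6.5345
714,6.5240
716,6.5137
718,6.5034
720,6.4933
722,6.4833
724,6.4735
726,6.4638
728,6.4542
730,6.4448
732,6.4355
734,6.4264
736,6.4175
738,6.4087
740,6.4000
742,6.3916
744,6.3835
746,6.3756
748,6.3680
750,6.3606
752,6.3534
754,6.3463
756,6.3392
758,6.3323
760,6.3253
762,6.3184
764,6.3114
766,6.3044
768,6.2972
770,6.2899
772,6.2824
774,6.2747
776,6.2668
778,6.2585
780,6.2500
782,6.2410
784,6.2317
786,6.2219
788,6.2119
790,6.2016
792,6.1912
794,6.1808
796,6.1704
798,6.1601
800,6.1500
802,6.1400
804,6.1300
806,6.1200
808,6.1100
810,6.1000
812,6.0900
814,6.0800
816,6.0700
818,6.0600
820,6.0500
822,6.0400
824,6.0300
826,6.0200
828,6.0100
830,6.0000
832,5.9900
834,5.9800
836,5.9700
838,5.9600
840,5.9500
842,5.9398
844,5.9294
846,5.9189
848,5.9083
850,5.8978
852,5.8875
854,5.8774
856,5.8677
858,5.8586
860,5.8500
862,5.8420
864,5.8346
866,5.8275
868,5.8207
870,5.8140
872,5.8075
874,5.8009
876,5.7942
878,5.7873
880,5.7800
882,5.7724
884,5.7647
886,5.7568
888,5.7488
890,5.7407
892,5.7325
894,5.7243
896,5.7162
898,5.7080
900,5.7000
902,5.6920
904,5.6840
906,5.6760
908,5.6680
910,5.6600
912,5.6520
914,5.6440
916,5.6360
918,5.6280
920,5.6200
922,5.6120
924,5.6040
926,5.5960
928,5.5880
930,5.5800
932,5.5720
934,5.5640
936,5.5560
938,5.5480
940,5.5400
942,5.5320
944,5.5240
946,5.5160
948,5.5080
950,5.5000
952,5.4920
954,5.4840
956,5.4760
958,5.4680
960,5.4600
962,5.4520
964,5.4440
966,5.4360
968,5.4280
970,5.4200
972,5.4120
974,5.4040
976,5.3960
978,5.3880
980,5.3800
982,5.3720
984,5.3640
986,5.3560
988,5.3480
990,5.3400
992,5.3320
994,5.3240
996,5.3160
998,5.3080
1000,5.3000
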