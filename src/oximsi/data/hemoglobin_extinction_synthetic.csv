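# SYNTHETIC hemoglobin extinction compilation (relative units).
# Constructed analytically for the oximsi package as a stand-in for published
# oxy-/deoxy-hemoglobin extinction tables: it reproduces the qualitative band
# structure of adult hemoglobin in the visible and near-infrared --
# oxyhemoglobin alpha/beta bands near 577/542 nm, the broad deoxyhemoglobin
# band near 555 nm, Soret-edge rise below 500 nm, a ~10x deoxy/oxy contrast at
# 660 nm, a single NIR isosbestic crossing near 800 nm, and oxy > deoxy at
# 940 nm -- but the magnitudes are in arbitrary relative units, not molar
# extinction coefficients. Columns: wavelength_nm, epsilon_oxy, epsilon_deoxy.
# Range 450-1000 nm, 2 nm spacing.
wavelength_nm,epsilon_oxy,epsilon_deoxy
450.0,55.307107,75.152002
452.0,52.252599,70.608148
454.0,49.367762,66.339617
456.0,46.643173,62.329729
458.0,44.069932,58.562816
460.0,41.639635,55.024160
462.0,39.344344,51.699933
464.0,37.176559,48.577149
466.0,35.129201,45.643605
468.0,33.195582,42.887843
470.0,31.369386,40.299099
472.0,29.644647,37.867266
474.0,28.015733,35.582856
476.0,26.477325,33.436966
478.0,25.024404,31.421254
480.0,23.652237,29.527915
482.0,22.356371,27.749667
484.0,21.132635,26.079755
486.0,19.977160,24.511961
488.0,18.886428,23.040645
490.0,17.857365,21.660812
492.0,16.887524,20.368212
494.0,15.975377,19.159495
496.0,15.120797,18.032420
498.0,14.325771,16.986130
500.0,13.595432,16.021499
502.0,12.939426,15.141550
504.0,12.373628,14.351934
506.0,11.922070,13.661435
508.0,11.618850,13.082476
510.0,11.509586,12.631547
512.0,11.651796,12.329476
514.0,12.113489,12.201437
516.0,12.969205,12.276594
518.0,14.292970,12.587242
520.0,16.148044,13.167374
522.0,18.574048,14.050599
524.0,21.572872,15.267423
526.0,25.095590,16.841964
528.0,29.033183,18.788284
530.0,33.213907,21.106617
532.0,37.409541,23.779841
534.0,41.351454,26.770634
536.0,44.755601,30.019743
538.0,47.353684,33.445772
540.0,48.926165,36.946799
542.0,49.332155,40.403953
544.0,48.531690,43.686907
546.0,46.597419,46.660983
548.0,43.714901,49.195376
550.0,40.172695,51.171805
552.0,36.344462,52.492791
554.0,32.664795,53.088763
556.0,29.598569,52.923255
558.0,27.601424,51.995645
560.0,27.068254,50.341160
562.0,28.269258,48.028120
564.0,31.279724,45.152744
566.0,35.918777,41.832036
568.0,41.719502,38.195506
570.0,47.953102,34.376507
572.0,53.719326,30.504018
574.0,58.095514,26.695519
576.0,60.313650,23.051508
578.0,59.918997,19.651908
580.0,56.863653,16.554451
582.0,51.506161,13.794880
584.0,44.517893,11.388678
586.0,36.726459,9.333905
588.0,28.943746,7.614718
590.0,21.825402,6.205140
592.0,15.791888,5.072719
594.0,11.017380,4.181807
596.0,7.471986,3.496271
598.0,4.991795,2.981567
600.0,3.351414,2.606171
602.0,2.321502,2.342418
604.0,1.704177,2.166860
606.0,1.347634,2.060246
608.0,1.145985,2.007239
610.0,1.031209,1.995976
612.0,0.962748,2.017561
614.0,0.918024,2.065539
616.0,0.885247,2.135408
618.0,0.858616,2.224191
620.0,0.835420,2.330072
622.0,0.814442,2.452113
624.0,0.795141,2.590022
626.0,0.777268,2.743993
628.0,0.760687,2.914580
630.0,0.745313,3.102619
632.0,0.731077,3.309168
634.0,0.717921,3.535474
636.0,0.705789,3.782957
638.0,0.694631,4.053197
640.0,0.684397,4.347934
642.0,0.675043,4.282946
644.0,0.666526,4.219395
646.0,0.658805,4.157224
648.0,0.651842,4.096380
650.0,0.645601,4.036813
652.0,0.640047,3.978478
654.0,0.635147,3.921331
656.0,0.630872,3.865331
658.0,0.627192,3.810440
660.0,0.624079,3.756620
662.0,0.621508,3.703836
664.0,0.619454,3.652055
666.0,0.617892,3.601245
668.0,0.616802,3.551377
670.0,0.616162,3.502420
672.0,0.615952,3.454349
674.0,0.616152,3.407137
676.0,0.616744,3.360759
678.0,0.617711,3.315191
680.0,0.619036,3.270412
682.0,0.620704,3.226398
684.0,0.622698,3.183130
686.0,0.625005,3.140588
688.0,0.627611,3.098753
690.0,0.630502,3.057607
692.0,0.633665,3.017132
694.0,0.637088,2.977312
696.0,0.640758,2.938132
698.0,0.644665,2.899576
700.0,0.648796,2.861629
702.0,0.653142,2.824277
704.0,0.657691,2.787507
706.0,0.662433,2.751305
708.0,0.667359,2.715660
710.0,0.672459,2.680560
712.0,0.677722,2.645992
714.0,0.683141,2.611945
716.0,0.688706,2.578410
718.0,0.694408,2.545374
720.0,0.700239,2.512829
722.0,0.706190,2.480765
724.0,0.712254,2.449172
726.0,0.718421,2.418041
728.0,0.724685,2.387364
730.0,0.731037,2.357131
732.0,0.737470,2.327335
734.0,0.743977,2.297968
736.0,0.750549,2.269022
738.0,0.757181,2.240490
740.0,0.763865,2.212363
742.0,0.770594,2.184636
744.0,0.777362,2.157301
746.0,0.784162,2.130351
748.0,0.790988,2.103781
750.0,0.797833,2.077583
752.0,0.804691,2.051751
754.0,0.811557,2.026280
756.0,0.818425,2.001163
758.0,0.825289,1.976395
760.0,0.832143,1.951970
762.0,0.838983,1.927883
764.0,0.845803,1.904128
766.0,0.852599,1.880700
768.0,0.859365,1.857595
770.0,0.866097,1.834807
772.0,0.872791,1.812330
774.0,0.879443,1.790162
776.0,0.886048,1.768296
778.0,0.892602,1.746728
780.0,0.899102,1.725454
782.0,0.905545,1.704469
784.0,0.911927,1.683770
786.0,0.918245,1.663351
788.0,0.924495,1.643209
790.0,0.930676,1.623340
792.0,0.936785,1.603740
794.0,0.942818,1.584404
796.0,0.948775,1.565330
798.0,0.954653,1.546512
800.0,0.960450,1.527949
802.0,0.966164,1.509635
804.0,0.971794,1.491567
806.0,0.977338,1.473743
808.0,0.982795,1.456158
810.0,0.988164,1.438809
812.0,0.993445,1.421692
814.0,0.998635,1.404806
816.0,1.003735,1.388145
818.0,1.008745,1.371708
820.0,1.013662,1.355491
822.0,1.018489,1.339490
824.0,1.023223,1.323704
826.0,1.027866,1.308129
828.0,1.032417,1.292761
830.0,1.036877,1.277599
832.0,1.041245,1.262640
834.0,1.045522,1.247880
836.0,1.049709,1.233317
838.0,1.053806,1.218948
840.0,1.057814,1.204771
842.0,1.061733,1.190782
844.0,1.065565,1.176980
846.0,1.069309,1.163362
848.0,1.072968,1.149925
850.0,1.076541,1.136667
852.0,1.080030,1.123586
854.0,1.083436,1.110678
856.0,1.086760,1.097943
858.0,1.090004,1.085376
860.0,1.093167,1.072977
862.0,1.096252,1.060743
864.0,1.099260,1.048671
866.0,1.102192,1.036760
868.0,1.105049,1.025007
870.0,1.107832,1.013410
872.0,1.110544,1.001967
874.0,1.113184,0.990676
876.0,1.115755,0.979535
878.0,1.118258,0.968543
880.0,1.120694,0.957696
882.0,1.123065,0.946993
884.0,1.125371,0.936432
886.0,1.127615,0.926011
888.0,1.129797,0.915728
890.0,1.131918,0.905582
892.0,1.133981,0.895571
894.0,1.135987,0.885693
896.0,1.137936,0.875945
898.0,1.139831,0.866327
900.0,1.141671,0.856836
902.0,1.143459,0.847472
904.0,1.145197,0.838231
906.0,1.146884,0.829113
908.0,1.148522,0.820116
910.0,1.150113,0.811238
912.0,1.151658,0.802478
914.0,1.153158,0.793835
916.0,1.154614,0.785305
918.0,1.156027,0.776889
920.0,1.157398,0.768584
922.0,1.158728,0.760390
924.0,1.160019,0.752304
926.0,1.161272,0.744325
928.0,1.162487,0.736452
930.0,1.163665,0.728684
932.0,1.164808,0.721018
934.0,1.165917,0.713454
936.0,1.166992,0.705990
938.0,1.168034,0.698625
940.0,1.169045,0.691358
942.0,1.170025,0.684187
944.0,1.170975,0.677111
946.0,1.171896,0.670129
948.0,1.172788,0.663239
950.0,1.173653,0.656441
952.0,1.174492,0.649732
954.0,1.175304,0.643113
956.0,1.176092,0.636581
958.0,1.176855,0.630136
960.0,1.177594,0.623776
962.0,1.178310,0.617501
964.0,1.179004,0.611308
966.0,1.179676,0.605198
968.0,1.180327,0.599169
970.0,1.180958,0.593219
972.0,1.181569,0.587349
974.0,1.182161,0.581556
976.0,1.182734,0.575839
978.0,1.183289,0.570199
980.0,1.183827,0.564633
982.0,1.184348,0.559141
984.0,1.184852,0.553722
986.0,1.185340,0.548375
988.0,1.185813,0.543098
990.0,1.186271,0.537891
992.0,1.186714,0.532754
994.0,1.187143,0.527684
996.0,1.187558,0.522681
998.0,1.187960,0.517745
1000.0,1.188350,0.512874
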