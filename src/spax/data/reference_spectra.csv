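wavelength_nm,collagen3,hbo2,hb,water,fat
680,0.06,0.203124638162,0.275920169818,0.0152108419692,0.052667570167
685,0.06,0.20220602374,0.297513105525,0.0152108419692,0.0527282965499
690,0.06,0.206117748256,0.325176658341,0.0152108419692,0.0528754257856
695,0.06,0.215451959851,0.359683615267,0.0152108419692,0.0532083870907
700,0.06,0.229670169482,0.40155909823,0.0152108419692,0.0539116918798
705,0.06,0.247313329431,0.450947994838,0.0152108419692,0.0552970123441
710,0.06,0.266525785071,0.507487598355,0.0152108419692,0.0578386083815
715,0.06,0.285640506143,0.570205506723,0.0152108419692,0.0621752371743
720,0.0600000000001,0.303579877907,0.637464250395,0.0152108419692,0.0690428557859
725,0.0600000000002,0.319960367721,0.706971839243,0.0152108419692,0.079108806798
730,0.0600000000009,0.334948418927,0.775870983442,0.0152108419692,0.0927095107413
735,0.0600000000034,0.349004967449,0.840909555083,0.0152108419692,0.109548413509
740,0.0600000000131,0.362650878324,0.898682271221,0.0152108419692,0.128468173625
745,0.0600000000478,0.37632258244,0.94592075226,0.0152108419693,0.147434027852
750,0.0600000001693,0.390321217987,0.979798605515,0.0152108419695,0.16382086367
755,0.0600000005786,0.404822575012,0.998212403218,0.0152108419704,0.174982985024
760,0.0600000019108,0.419911013868,1,0.0152108419733,0.178947368421
765,0.0600000060953,0.435613250298,0.985064960209,0.0152108419831,0.174982985024
770,0.0600000187812,0.451922457777,0.95438890134,0.0152108420142,0.16382086367
775,0.0600000559008,0.468812325229,0.909929998647,0.0152108421109,0.147434027852
780,0.0600001607215,0.486244142115,0.854422655297,0.0152108424035,0.128468173625
785,0.0600004463668,0.504170059223,0.791107266173,0.0152108432626,0.109548413509
790,0.0600011974903,0.522534635005,0.723427583099,0.0152108457133,0.0927095107413
795,0.0600031032316,0.541275787511,0.654735111823,0.0152108525048,0.079108806798
800,0.0600077681656,0.560325648564,0.588035353304,0.0152108707872,0.0690428557859
805,0.0600187838608,0.579611502279,0.525800965678,0.0152109185917,0.0621752371743
810,0.0600438746184,0.599056852843,0.469864368824,0.0152110400028,0.0578386083815
815,0.0600989928769,0.618582611421,0.421389525736,0.0152113394907,0.0552970123441
820,0.0602157528995,0.638108369994,0.380911894313,0.015212056965,0.0539116918798
825,0.0604542254238,0.657553720524,0.348428384644,0.0152137261853,0.0532083870907
830,0.060923736999,0.676839574034,0.323516168989,0.0152174973185,0.0528754257856
835,0.0618146268881,0.695889433959,0.305460063136,0.0152257700502,0.0527282965499
840,0.0634434077041,0.714630580759,0.293371957747,0.0152433901841,0.0526675701675
845,0.0663117771136,0.732995129932,0.28629113289,0.0152798247082,0.0526441447637
850,0.0711757573641,0.750920932736,0.283259954726,0.0153529582256,0.0526356953253
855,0.0791145631362,0.768352297475,0.283374409252,0.0154954434458,0.0526328485445
860,0.0915801284008,0.785240518489,0.285812547899,0.0157648557974,0.0526320081021
865,0.110399416532,0.801544209241,0.289845986177,0.016259162585,0.0526324176547
870,0.137696101551,0.817229444553,0.294840226277,0.0171390669894,0.0526385978823
875,0.17570045063,0.832269724543,0.30024909756,0.0186583982675,0.0526859552266
880,0.22643052186,0.846645778805,0.305607442906,0.0212026112993,0.0529792618687
885,0.291255995982,0.860345233677,0.310524726729,0.02533336725,0.0544604305136
890,0.370395296221,0.873362168005,0.31468082485,0.0318339688677,0.0605447754931
895,0.462438353099,0.885696583751,0.317824092563,0.0417463029123,0.0807960997444
900,0.564017594509,0.897353817318,0.319771003731,0.0563855584734,0.135088979887
905,0.669753264247,0.908343915815,0.320406232074,0.0773155700943,0.251210787828
910,0.772565305664,0.918681000019,0.319681965535,0.106266885921,0.446013837699
915,0.864372685333,0.92838263276,0.317615429209,0.14498342725,0.693653117416
920,0.937105952674,0.937469208148,0.314283949772,0.194993253239,0.911857427472
925,0.983865830372,0.945963373714,0.309817332568,0.257314588996,1
930,1,0.95388949435,0.304387759867,0.332128097875,0.911857427472
935,0.983865830372,0.96127316398,0.298197790392,0.418466368805,0.693653117416
940,0.937105952674,0.968140768342,0.291467301803,0.51398602372,0.446013837699
945,0.864372685333,0.974519100091,0.284420346625,0.614890625999,0.251210787827
950,0.772565305664,0.98043502567,0.277272886289,0.716059178832,0.135088979885
955,0.669753264247,0.985915202038,0.270222243524,0.81140456867,0.0807960997343
960,0.564017594509,0.990985840348,0.263438899663,0.894442913662,0.0605447754382
965,0.462438353099,0.995672512991,0.257060997857,0.959007330477,0.0544604302343
970,0.370395296221,1,0.251191634762,1,0.0529792605363
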