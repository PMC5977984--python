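feature_id	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12
miR-1	6.8136623574131185	6.997581307428893	6.8490211541065324	6.213051440585178	6.0871652663144875	6.525164201748877	5.263410570609675	5.157761334881254	5.548090967516133	5.230258337173724	5.196933161406987	4.7856085388587735
miR-2	6.828059951160464	7.605696737403756	7.1750487826195055	7.4038310967931125	6.747448209706274	7.0294638409463985	8.273047571694246	8.427671456425507	8.931293985021734	8.216200664192538	8.50014721278427	8.70951163335894
miR-3	4.444445400342577	4.569299563923325	4.578428029554248	4.770428062733142	4.515610127309049	4.726664695819278	4.662032250462292	4.772357268659822	4.7124695082383194	5.142291708376611	4.445883670977128	5.004742641502102
miR-4	7.346506369876745	7.179912245911925	7.83064843862001	7.335438326605463	7.350999336291048	7.050684992983967	6.8378310606561925	7.657580380242675	7.117710184622882	7.700771994797119	8.02174028640579	7.432850714054425
miR-5	5.761394287350306	6.217638570468243	6.327897359401447	6.020841704638476	6.104618165515739	6.499960036889826	6.4790144118426864	6.3123722867120176	5.839458555112856	6.083276146937818	6.280254013496618	6.0358190577014765
miR-6	7.896140352338202	7.8495291149733175	7.889543085249358	7.877664294527474	7.9438123150527105	8.422848901202043	7.83895313663867	8.345216352369654	8.204421129332767	8.121070636502633	7.830925174528348	7.942137467156827
miR-7	8.710327506090715	8.147981277456454	8.279723228164125	8.31717039381034	8.434953367135044	8.047005994932073	7.9352016323872805	8.100376711674365	8.040015088762816	8.355463918836604	8.175144024915005	8.190042040321124
miR-8	8.883207595233136	9.208215064264568	8.6769166058904	8.696197923391615	9.10524399896265	8.80778172707791	8.94796818569683	8.621008260867109	8.846704092347988	8.969254908614966	8.441473778379013	8.631224539568278
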