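material,energy_keV,mu_per_cm,density_g_cm3
acrylic,20,0.76767175473766591,1.1899999999999999
acrylic,30,0.3842602664289213,1.1899999999999999
acrylic,40,0.28572036697877901,1.1899999999999999
acrylic,50,0.24663661818091989,1.1899999999999999
acrylic,60,0.22623142137544092,1.1899999999999999
acrylic,70,0.21334967677521718,1.1899999999999999
acrylic,80,0.2040794723861804,1.1899999999999999
acrylic,90,0.19679392714843885,1.1899999999999999
acrylic,100,0.19072438339027006,1.1899999999999999
acrylic,110,0.18546885413826292,1.1899999999999999
acrylic,120,0.18079858332105081,1.1899999999999999
acrylic,130,0.1765736392339774,1.1899999999999999
acrylic,140,0.17270288730750358,1.1899999999999999
acrylic,150,0.1691236495978469,1.1899999999999999
aluminum,20,9.3232856451610395,2.6989999999999998
aluminum,30,3.0827575454084686,2.6989999999999998
aluminum,40,1.5530401342959452,2.6989999999999998
aluminum,50,1.0001390009341362,2.6989999999999998
aluminum,60,0.74935515067587355,2.6989999999999998
aluminum,70,0.61669174777127145,2.6989999999999998
aluminum,80,0.53805142160121355,2.6989999999999998
aluminum,90,0.48709941314469118,2.6989999999999998
aluminum,100,0.45163771577384271,2.6989999999999998
aluminum,110,0.42547341793969068,2.6989999999999998
aluminum,120,0.40522436609768359,2.6989999999999998
aluminum,130,0.38892957162972858,2.6989999999999998
aluminum,140,0.37539342433534889,2.6989999999999998
aluminum,150,0.36385485598123768,2.6989999999999998
bone50,20,4.2426031500982333,1.3999999999999999
bone50,30,1.4580256593416099,1.3999999999999999
bone50,40,0.77352439509249626,1.3999999999999999
bone50,50,0.52465063825862579,1.3999999999999999
bone50,60,0.41063364810260433,1.3999999999999999
bone50,70,0.3494357118618952,1.3999999999999999
bone50,80,0.31246710298319202,1.3999999999999999
bone50,90,0.28797325739080537,1.3999999999999999
bone50,100,0.27050318243529503,1.3999999999999999
bone50,110,0.25728444739773731,1.3999999999999999
bone50,120,0.24679903496156783,1.3999999999999999
bone50,130,0.23816370274407142,1.3999999999999999
bone50,140,0.23083747726485032,1.3999999999999999
bone50,150,0.22447402582890097,1.3999999999999999
delrin,20,1.0641573127536472,1.4199999999999999
delrin,30,0.50163637033868358,1.4199999999999999
delrin,40,0.35851642519154325,1.4199999999999999
delrin,50,0.30280542989183734,1.4199999999999999
delrin,60,0.27446137666888165,1.4199999999999999
delrin,70,0.2570704378456487,1.4199999999999999
delrin,80,0.24488492223207667,1.4199999999999999
delrin,90,0.23552079455667116,1.4199999999999999
delrin,100,0.22785645095824417,1.4199999999999999
delrin,110,0.22130897302384231,1.4199999999999999
delrin,120,0.21554942504764812,1.4199999999999999
delrin,130,0.21037870841721823,1.4199999999999999
delrin,140,0.20566875173990376,1.4199999999999999
delrin,150,0.20133267287790069,1.4199999999999999
ldpe,20,0.44447956394486365,0.92000000000000004
ldpe,30,0.25815084916405601,0.92000000000000004
ldpe,40,0.20859333068389083,0.92000000000000004
ldpe,50,0.18772542263901101,0.92000000000000004
ldpe,60,0.17597763684859227,0.92000000000000004
ldpe,70,0.16798364142370734,0.92000000000000004
ldpe,80,0.16185192965309367,0.92000000000000004
ldpe,90,0.15678861468167138,0.92000000000000004
ldpe,100,0.15241310211830789,0.92000000000000004
ldpe,110,0.14852215657307122,0.92000000000000004
ldpe,120,0.14499692690375202,0.92000000000000004
ldpe,130,0.14176228164266524,0.92000000000000004
ldpe,140,0.13876745333167426,0.92000000000000004
ldpe,150,0.13597614829848625,0.92000000000000004
pmma,20,0.76767175473766591,1.1899999999999999
pmma,30,0.3842602664289213,1.1899999999999999
pmma,40,0.28572036697877901,1.1899999999999999
pmma,50,0.24663661818091989,1.1899999999999999
pmma,60,0.22623142137544092,1.1899999999999999
pmma,70,0.21334967677521718,1.1899999999999999
pmma,80,0.2040794723861804,1.1899999999999999
pmma,90,0.19679392714843885,1.1899999999999999
pmma,100,0.19072438339027006,1.1899999999999999
pmma,110,0.18546885413826292,1.1899999999999999
pmma,120,0.18079858332105081,1.1899999999999999
pmma,130,0.1765736392339774,1.1899999999999999
pmma,140,0.17270288730750358,1.1899999999999999
pmma,150,0.1691236495978469,1.1899999999999999
pmp,20,0.40988223572429044,0.85299999999999998
pmp,30,0.23805694522912405,0.85299999999999998
pmp,40,0.19235687683606364,0.85299999999999998
pmp,50,0.17311328163359604,0.85299999999999998
pmp,60,0.1622799180884856,0.85299999999999998
pmp,70,0.15490815798315929,0.85299999999999998
pmp,80,0.14925372539901499,0.85299999999999998
pmp,90,0.14458452791726017,0.85299999999999998
pmp,100,0.14054959579126119,0.85299999999999998
pmp,110,0.13696151303441051,0.85299999999999998
pmp,120,0.13371067962043293,0.85299999999999998
pmp,130,0.13072781215264156,0.85299999999999998
pmp,140,0.12796609480207366,0.85299999999999998
pmp,150,0.12539205891741487,0.85299999999999998
polystyrene,20,0.52106617257217347,1.05
polystyrene,30,0.29082272753044824,1.05
polystyrene,40,0.23024388608006363,1.05
polystyrene,50,0.20519707081266952,1.05
polystyrene,60,0.19140296325663478,1.05
polystyrene,70,0.18220886319064925,1.05
polystyrene,80,0.17527368337186963,1.05
polystyrene,90,0.16961771718567581,1.05
polystyrene,100,0.16477344946223735,1.05
polystyrene,110,0.16049285378314096,1.05
polystyrene,120,0.1566320978158173,1.05
polystyrene,130,0.15310115471559299,1.05
polystyrene,140,0.14983984752845644,1.05
polystyrene,150,0.14680563006042027,1.05
teflon,20,2.3038617421589378,2.1600000000000001
teflon,30,0.9379928134863833,2.1600000000000001
teflon,40,0.59702743510649681,2.1600000000000001
teflon,50,0.46910409059107594,2.1600000000000001
teflon,60,0.40746315828402846,2.1600000000000001
teflon,70,0.3720350640798914,2.1600000000000001
teflon,80,0.34882611790430174,2.1600000000000001
teflon,90,0.33206038583868763,2.1600000000000001
teflon,100,0.31904210707608993,2.1600000000000001
teflon,110,0.3083867852687584,2.1600000000000001
teflon,120,0.29932584749043589,2.1600000000000001
teflon,130,0.29140381163540235,2.1600000000000001
teflon,140,0.28433511009229112,2.1600000000000001
teflon,150,0.27793166005563663,2.1600000000000001
vacuum,20,0,0
vacuum,30,0,0
vacuum,40,0,0
vacuum,50,0,0
vacuum,60,0,0
vacuum,70,0,0
vacuum,80,0,0
vacuum,90,0,0
vacuum,100,0,0
vacuum,110,0,0
vacuum,120,0,0
vacuum,130,0,0
vacuum,140,0,0
vacuum,150,0,0
water,20,0.90587391246797011,1
water,30,0.40511324797331655,1
water,40,0.27867573656204531,1
water,50,0.23016915261042545,1
water,60,0.20599999999999999,1
water,70,0.19152476384535713,1
water,80,0.18162123822442569,1
water,90,0.17416902909374929,1
water,100,0.16817376492866157,1
water,110,0.16312110044426004,1
water,120,0.15872267275424645,1
water,130,0.15480537992084517,1
water,140,0.15125897186305973,1
water,150,0.14800949139478523,1
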