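order	family	genus	species	n	St
Anguilliformes	Congridae	Conger	Conger conger	1	1
Anguilliformes	Ophichthidae	Dalophis	Dalophis imberbis	1	1
Anguilliformes	Ophichthidae	Myrophis	Myrophis punctatus	1	1
Argentiniformes	Microstomatidae	Batylagoides	Batylagoides argyrogaster	2	1
Aulopiformes	Evermannellidae	Evermanella	Evermanella balbo	1	1
Aulopiformes	Paralepididae	Macroparalepis	Macroparalepis affinis	1	1
Aulopiformes	Scopelarchidae	Benthabella	Benthabella infans	1	1
Lophiiformes	Melanocetidae	Melanocetus	Melanocetus johnsonii	1	1
Myctophiformes	Myctophidae	Benthosema	Benthosema suborbitale	4	1
Myctophiformes	Myctophidae	Bolinichthys	Bolinichthys indicus	5	3
Myctophiformes	Myctophidae	Ceratoscopelus	Ceratoscopelus maderensis	1	1
Myctophiformes	Myctophidae	Diaphus	Diaphus brachycephalus	1	1
Myctophiformes	Myctophidae	Diaphus	Diaphus holti	1	1
Myctophiformes	Myctophidae	Diaphus	Diaphus rafinesquii	8	2
Myctophiformes	Myctophidae	Diogenichthys	Diogenichthys atlanticus	3	2
Myctophiformes	Myctophidae	Hygophum	Hygophum hygomii	22	3
Myctophiformes	Myctophidae	Hygophum	Hygophum macrochir	24	5
Myctophiformes	Myctophidae	Hygophum	Hygophum taaningi	1	1
Myctophiformes	Myctophidae	Lampadena	Lampadena pontifex	1	1
Myctophiformes	Myctophidae	Lampanyctus	Lampanyctus alatus	1	1
Myctophiformes	Myctophidae	Lampanyctus	Lampanyctus nobilis	1	1
Myctophiformes	Myctophidae	Lampanyctus	Lampanyctus pusillus	3	2
Myctophiformes	Myctophidae	Lepidophanes	Lepidophanes guentheri	4	1
Myctophiformes	Myctophidae	Lobianchia	Lobianchia dofleini	1	1
Myctophiformes	Myctophidae	Myctophum	Myctophum affine	1	1
Myctophiformes	Myctophidae	Myctophum	Myctophum asperum	1	1
Myctophiformes	Myctophidae	Myctophum	Myctophum obtusirostre	1	1
Myctophiformes	Myctophidae	Myctophum	Myctophum selenops	2	1
Myctophiformes	Myctophidae	Notolychrus	Notolychrus valdiviae	1	1
Myctophiformes	Myctophidae	Notoscopelus	Notoscopelus resplendens	5	2
Myctophiformes	Myctophidae	Symbolophorus	Symbolophorus veranyi	1	1
Myctophiformes	Myctophidae	Taanngichthys	Taanngichthys minimus	1	1
Pleuronectiformes	Pleuronectidae	Reinhardtius	Reinhardtius hippoglossoides	2	2
Scombriformes	Gempylidae	Diplospinus	Diplospinus multistriatus	2	1
Scorpaeniformes	Serranidae	Mycteroperca	Mycteroperca acutirostris	1	1
Stomiiformes	Gonostomatidae	Cyclothone	Cyclothone acclinidens	1	1
Stomiiformes	Gonostomatidae	Cyclothone	Cyclothone braueri	1	1
Stomiiformes	Gonostomatidae	Cyclothone	Cyclothone livida	1	1
Stomiiformes	Gonostomatidae	Gonostoma	Gonostoma denudatum	1	1
Stomiiformes	Gonostomatidae	Gonostoma	Gonostoma elongatum	2	1
Stomiiformes	Stomiidae	Astronethes	Astronethes richardsonii	1	1
Stomiiformes	Phosichthyidae	Vinciguerria	Vinciguerria nimbaria	2	2
Stromateiformes	Nomeidae	Cubiceps	Cubiceps baxteri	1	1
Stromateiformes	Nomeidae	Psenes	Psenes arafurensis	2	2
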