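TOY01	glycolysis-like cycle	M105	M106	M021	M185	M157	M208
TOY02	amino-acid shuttle	M214	M022	M016	M202	M192	M105	M054	M208	M128	M133	M107
TOY03	sugar interconversion	M055	M031	M136	M107	M113	M163	M109	M185	M228	M079	M162	M045
TOY04	fatty-acid chain	M153	M242	M137	M138	M134	M023	M111	M156	M019	M201	M240	M183
TOY05	nucleotide salvage	M173	M174	M184	M112	M168	M040
TOY06	redox couple web	M225	M171	M120	M230	M028	M021	M219	M088	M081	M238
TOY07	urea-like cycle	M161	M105	M182	M174	M119
TOY08	short-chain acid hub	M041	M186	M024	M220	M084	M071	M149	M235	M236	M139	M144	M108	M156	M034	M137
TOY09	sterol branch	M166	M055	M230	M215	M090	M076	M025	M009	M144	M057	M177	M075	M134	M034	M234	M132
TOY10	vitamin cofactor loop	M177	M023	M230	M091	M174	M226	M002	M063	M059	M208	M088
TOY11	glycan side route	M118	M181	M217	M138	M207	M048	M069	M222	M099	M174	M007	M163	M029	M021	M193
TOY12	pigment degradation chain	M069	M113	M199	M193	M057	M061
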