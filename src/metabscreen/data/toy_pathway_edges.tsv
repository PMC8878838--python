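# synthetic toy pathway edge list (pathway_id\tsource\ttarget); no real pathway content
TOY01	M208	M157
TOY01	M157	M021
TOY01	M021	M185
TOY01	M185	M105
TOY01	M105	M106
TOY01	M208	M021
TOY01	M157	M208
TOY02	M054	M202
TOY02	M202	M128
TOY02	M128	M016
TOY02	M016	M133
TOY02	M133	M105
TOY02	M105	M022
TOY02	M022	M208
TOY02	M208	M192
TOY02	M192	M107
TOY02	M107	M214
TOY02	M192	M133
TOY03	M079	M185
TOY03	M185	M113
TOY03	M113	M162
TOY03	M162	M107
TOY03	M107	M136
TOY03	M136	M228
TOY03	M228	M045
TOY03	M045	M031
TOY03	M031	M055
TOY03	M055	M109
TOY03	M109	M163
TOY03	M228	M163
TOY03	M109	M228
TOY03	M136	M031
TOY04	M137	M240
TOY04	M240	M134
TOY04	M134	M019
TOY04	M019	M156
TOY04	M156	M111
TOY04	M111	M023
TOY04	M023	M138
TOY04	M138	M153
TOY04	M153	M201
TOY04	M201	M183
TOY04	M183	M242
TOY04	M019	M183
TOY04	M183	M134
TOY04	M138	M019
TOY04	M153	M138
TOY05	M173	M112
TOY05	M112	M174
TOY05	M174	M040
TOY05	M040	M168
TOY05	M168	M184
TOY05	M112	M040
TOY06	M120	M088
TOY06	M088	M171
TOY06	M171	M028
TOY06	M028	M238
TOY06	M238	M021
TOY06	M021	M225
TOY06	M225	M219
TOY06	M219	M230
TOY06	M230	M081
TOY06	M088	M021
TOY07	M161	M119
TOY07	M119	M182
TOY07	M182	M105
TOY07	M105	M174
TOY07	M161	M105
TOY08	M024	M236
TOY08	M236	M034
TOY08	M034	M149
TOY08	M149	M220
TOY08	M220	M144
TOY08	M144	M139
TOY08	M139	M156
TOY08	M156	M071
TOY08	M071	M084
TOY08	M084	M137
TOY08	M137	M235
TOY08	M235	M108
TOY08	M108	M186
TOY08	M186	M041
TOY08	M084	M235
TOY08	M220	M137
TOY09	M009	M076
TOY09	M076	M215
TOY09	M215	M090
TOY09	M090	M132
TOY09	M132	M230
TOY09	M230	M177
TOY09	M177	M075
TOY09	M075	M055
TOY09	M055	M166
TOY09	M166	M025
TOY09	M025	M134
TOY09	M134	M234
TOY09	M234	M144
TOY09	M144	M057
TOY09	M057	M034
TOY09	M075	M076
TOY10	M226	M177
TOY10	M177	M002
TOY10	M002	M063
TOY10	M063	M208
TOY10	M208	M088
TOY10	M088	M059
TOY10	M059	M023
TOY10	M023	M174
TOY10	M174	M091
TOY10	M091	M230
TOY10	M174	M023
TOY10	M023	M177
TOY10	M023	M230
TOY11	M118	M181
TOY11	M181	M021
TOY11	M021	M222
TOY11	M222	M163
TOY11	M163	M217
TOY11	M217	M193
TOY11	M193	M174
TOY11	M174	M207
TOY11	M207	M069
TOY11	M069	M099
TOY11	M099	M007
TOY11	M007	M029
TOY11	M029	M048
TOY11	M048	M138
TOY11	M163	M181
TOY11	M193	M118
TOY11	M099	M217
TOY11	M029	M007
TOY11	M069	M174
TOY11	M163	M118
TOY12	M199	M061
TOY12	M061	M113
TOY12	M113	M069
TOY12	M069	M057
TOY12	M057	M193
TOY12	M199	M057
TOY12	M193	M061
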