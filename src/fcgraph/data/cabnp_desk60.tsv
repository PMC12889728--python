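parcel_id	parcel_name	network_index	network_name
P001	P001	1	Primary Visual
P002	P002	1	Primary Visual
P003	P003	1	Primary Visual
P004	P004	1	Primary Visual
P005	P005	1	Primary Visual
P006	P006	2	Secondary Visual
P007	P007	2	Secondary Visual
P008	P008	2	Secondary Visual
P009	P009	2	Secondary Visual
P010	P010	2	Secondary Visual
P011	P011	3	Somatomotor
P012	P012	3	Somatomotor
P013	P013	3	Somatomotor
P014	P014	3	Somatomotor
P015	P015	3	Somatomotor
P016	P016	4	Cingulo-Opercular
P017	P017	4	Cingulo-Opercular
P018	P018	4	Cingulo-Opercular
P019	P019	4	Cingulo-Opercular
P020	P020	4	Cingulo-Opercular
P021	P021	5	Dorsal Attention
P022	P022	5	Dorsal Attention
P023	P023	5	Dorsal Attention
P024	P024	5	Dorsal Attention
P025	P025	5	Dorsal Attention
P026	P026	6	Language
P027	P027	6	Language
P028	P028	6	Language
P029	P029	6	Language
P030	P030	6	Language
P031	P031	7	Frontoparietal
P032	P032	7	Frontoparietal
P033	P033	7	Frontoparietal
P034	P034	7	Frontoparietal
P035	P035	7	Frontoparietal
P036	P036	8	Auditory
P037	P037	8	Auditory
P038	P038	8	Auditory
P039	P039	8	Auditory
P040	P040	8	Auditory
P041	P041	9	Default Mode
P042	P042	9	Default Mode
P043	P043	9	Default Mode
P044	P044	9	Default Mode
P045	P045	9	Default Mode
P046	P046	10	Posterior Multimodal
P047	P047	10	Posterior Multimodal
P048	P048	10	Posterior Multimodal
P049	P049	10	Posterior Multimodal
P050	P050	10	Posterior Multimodal
P051	P051	11	Ventral Multimodal
P052	P052	11	Ventral Multimodal
P053	P053	11	Ventral Multimodal
P054	P054	11	Ventral Multimodal
P055	P055	11	Ventral Multimodal
P056	P056	12	Orbito-Affective
P057	P057	12	Orbito-Affective
P058	P058	12	Orbito-Affective
P059	P059	12	Orbito-Affective
P060	P060	12	Orbito-Affective
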