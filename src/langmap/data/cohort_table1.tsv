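patient_id	age_bin	handedness	laterality_index	tumor_location	tumor_volume_ml	pathology
RS_003	40-45	R	-0.11	Left basal ganglia	8.7	Glioblastoma
RS_003	40-45	R	-0.11	Left temporal lobe	4.8	Glioblastoma
RS_004	20-25	R	0.04	Left frontal lobe	56.2	Anaplastic glioma
RS_005	35-40	NA	-0.08	Left frontal lobe	1.2	Anaplastic mixed oligoastrocytoma
RS_005	35-40	NA	-0.08	Left frontal lobe	0.2	Anaplastic mixed oligoastrocytoma
RS_006	35-40	NA	0.32	Left inferior frontal lobe	81.1	Anaplastic mixed oligoastrocytoma
RS_007	60-65	R	0.15	Left parieto-occipital	85.1	Glioblastoma
RS_009	60-65	R	0.10	Left peri-trigonal area	147	Glioblastoma
RS_011	20-25	R	0.67	Left frontotemporal	56.4	Mixed oligoastrocytoma
RS_012	40-45	R	0.36	Left frontal lobe	7.8	Anaplastic oligodendroglioma
RS_014	40-45	R	0.37	Left frontal/insular lobe	69.2	Oligodendroglioma
RS_015	60-65	NA	0.05	Left frontal lobe	34.7	Mixed oligoastrocytoma
RS_016	55-60	NA	0.01	Left insula	15.2	Glioblastoma
RS_017	50-55	R	0.08	Left frontal lobe	64.3	Mixed oligoastrocytoma
RS_018	35-40	R	0.35	Left frontal lobe	13.5	Oligodendroglioma
RS_019	30-35	R	0.25	Right frontoparietal	207	Anaplastic oligodendroglioma
RS_020	50-55	R	0.24	Left temporal lobe	19.9	Glioblastoma
RS_021	25-30	R	0.05	Left frontal lobe	63.3	Mixed oligoastrocytoma
RS_022	65-70	NA	0.02	Right frontal lobe	2.2	Metastatic lung carcinoma
RS_023	50-55	R	0.38	Left parietal/splenium	28.7	Oligodendroglioma
RS_024	55-60	R	0.25	Left frontal lobe	4.7	Anaplastic oligoastrocytoma
RS_027	45-50	L	0.48	Left temporal lobe	24.8	Low-grade diffuse glioma
RS_029	50-55	R	0.11	Left frontal lobe	14.5	Oligodendroglioma
RS_030	70-75	R	-0.14	Right basal ganglia/thalamus	16.6	Glioblastoma
RS_031	50-55	NA	0.53	Left thalamus	5.8	Glioblastoma
RS_032	45-50	R	0.79	Right temporal lobe	5.7	Glioblastoma
RS_033	35-40	R	0.64	Left frontal lobe	185	Mixed oligoastrocytoma
RS_034	55-60	NA	0.22	Left temporal lobe	24.9	Meningioma
RS_035	25-30	R	0.13	Left temporal lobe	10.1	Oligoastrocytoma
RS_039	25-30	L	0.18	Right parietal lobe	32.0	Mixed oligoastrocytoma
RS_040	35-40	R	0.29	Right sylvian fissure	31.5	Ependymoma
RS_041	40-45	NA	0.54	Left frontal lobe	23.3	Mixed oligoastrocytoma
RS_042	60-65	R	0.17	Left parietal lobe	0.7	Glioblastoma
RS_043	30-35	R	0.46	Right temporal lobe	4.0	Low-grade glioneuronal tumor
RS_044	20-25	R	0.40	Left frontal lobe	0.4	Ganglioglioma
RS_045	25-30	L	0.33	Bilateral frontal lobes (left>right)	118	Anaplastic astrocytoma
RS_047	55-60	NA	0.16	Left frontal lobe	66.2	Glioblastoma
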