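# Case characteristics for the 24-case canine acanthomatous ameloblastoma cohort.
# read_depth is the depth at the mutated base; vaf the variant allele fraction.
# Empty mutation = no driver hotspot mutation identified; empty read_depth/vaf =
# value not measured by exome sequencing (Sanger-confirmed cases).
case_id	location	breed	age_years	sex	weight_kg	tissue	mutation	read_depth	vaf
CAA-01	Mandible	German Shepherd	8	MC	42	FFPE
CAA-02	Mandible	Labrador Retriever	13	FS	31	FFPE
CAA-03	Mandible	Labrador Retriever	11	FS	33	FFPE	HRAS-Q61R	72	0.278
CAA-04	Mandible	Pit Bull Terrier	10	FS	27	FFPE	HRAS-Q61R
CAA-05	Mandible	Shetland Sheepdog	11	MC	22	FFPE	BRAF-V595E	197	0.289
CAA-06	Mandible	Border Collie	8	MC	29	FFPE	HRAS-Q61R	63	0.270
CAA-07	Mandible	Australian Shepherd	9	MC	31	FFPE	HRAS-G13R	38	0.421
CAA-08	Mandible	Basset Hound	15	MC	36	FFPE	HRAS-Q61R
CAA-09	Mandible	Cocker Spaniel	9	FS	15	FFPE	HRAS-Q61R	95	0.263
CAA-10	Mandible	Husky mix	10	FS	39	FFPE
CAA-11	Mandible	Chesapeake Bay Retriever	6	MC	33	FFPE	HRAS-Q61R
CAA-12	Maxilla	Samoyed	10	FS	36	FFPE	HRAS-Q61R	63	0.238
CAA-13	Maxilla	Beagle	10	MC	12	FFPE
CAA-14	Maxilla	Collie	11	MC	30	FFPE
CAA-15	Maxilla	Labrador Retriever	12	MC	39	FFPE	BRAF-V595E
CAA-16	Maxilla	Collie	11	MC	31	FFPE
CAA-17	Maxilla	Standard Poodle	7	MC	25	FFPE
CAA-18	Maxilla	Labrador Retriever	11	FS	26	FFPE	HRAS-Q61R	90	0.267
CAA-19	Maxilla	English Bulldog	10	MC		FFPE	HRAS-Q61R	57	0.456
CAA-20	Maxilla	Beagle mix	5	MC	17	FFPE	HRAS-Q61R	101	0.109
CAA-21	Mandible	Labrador Retriever	8	FS	31	fresh	HRAS-Q61R
CAA-22	Mandible	Terrier mix	8	FS	22	fresh	HRAS-Q61R
CAA-23	Mandible	Great Dane	9	FS	53	fresh	HRAS-Q61R
CAA-24	Mandible	Standard Poodle	3	MC	40	fresh	HRAS-Q61R
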