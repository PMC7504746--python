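surface_form	canonical_id	entity_type
IBC	D_IBC	disease
inflammatory breast cancer	D_IBC	disease
Retinoblastoma	H01513	disease
Neuroblastoma	H00043	disease
Medulloblastoma	H01667	disease
Glioma	H00042	disease
Meningioma	H01556	disease
Osteosarcoma	H00036	disease
Ewing sarcoma	H00035	disease
Rhabdomyosarcoma	H00037	disease
Synovial sarcoma	H00050	disease
Angiosarcoma	H01666	disease
B-cell acute lymphocytic leukemia	H00001	disease
T-cell acute lymphocytic leukemia	H00002	disease
Nasopharyngeal cancer	H00054	disease
Salivary gland cancer	H01508	disease
Tonsillar cancer	H01509	disease
Cancer of the anal canal	H00044	disease
Fallopian tube cancer	H01554	disease
Primary peritoneal carcinoma	H01665	disease
carboplatin	DB00958	drug
carmustine	DB00262	drug
cytarabine	DB00987	drug
dacarbazine	DB00851	drug
daunorubicin	DB00694	drug
docetaxel	DB01248	drug
doxorubicin	DB00997	drug
etoposide	DB00773	drug
fluorouracil	DB00544	drug
gefitinib	DB00317	drug
gemcitabine	DB00441	drug
hydroxyurea	DB01005	drug
ifosfamide	DB01181	drug
imatinib	DB00619	drug
lapatinib	DB01259	drug
methotrexate	DB00563	drug
mitoxantrone	DB01204	drug
octreotide	DB00104	drug
paclitaxel	DB01229	drug
prednisone	DB00635	drug
sunitinib	DB01268	drug
topotecan	DB01030	drug
vincristine	DB00541	drug
vinorelbine	DB00361	drug
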