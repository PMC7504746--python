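drug_id	drug_name	disease_id	disease_name	source
DB00958	carboplatin	H01513	Retinoblastoma	kegg
DB00773	etoposide	H01513	Retinoblastoma	kegg
DB00541	vincristine	H01513	Retinoblastoma	kegg
DB00997	doxorubicin	H00043	Neuroblastoma	kegg
DB00773	etoposide	H00043	Neuroblastoma	kegg
DB00958	carboplatin	H01667	Medulloblastoma	kegg
DB01030	topotecan	H01667	Medulloblastoma	kegg
DB00541	vincristine	H01667	Medulloblastoma	kegg
DB00262	carmustine	H00042	Glioma	kegg
DB00541	vincristine	H00042	Glioma	kegg
DB01005	hydroxyurea	H01556	Meningioma	kegg
DB00619	imatinib	H01556	Meningioma	kegg
DB00104	octreotide	H01556	Meningioma	kegg
DB00997	doxorubicin	H00036	Osteosarcoma	kegg
DB01181	ifosfamide	H00036	Osteosarcoma	kegg
DB00563	methotrexate	H00036	Osteosarcoma	kegg
DB00851	dacarbazine	H00035	Ewing sarcoma	kegg
DB00997	doxorubicin	H00035	Ewing sarcoma	kegg
DB00773	etoposide	H00035	Ewing sarcoma	kegg
DB01181	ifosfamide	H00035	Ewing sarcoma	kegg
DB00541	vincristine	H00035	Ewing sarcoma	kegg
DB00851	dacarbazine	H00037	Rhabdomyosarcoma	kegg
DB00997	doxorubicin	H00037	Rhabdomyosarcoma	kegg
DB01181	ifosfamide	H00037	Rhabdomyosarcoma	kegg
DB00619	imatinib	H00037	Rhabdomyosarcoma	kegg
DB01268	sunitinib	H00037	Rhabdomyosarcoma	kegg
DB00851	dacarbazine	H00050	Synovial sarcoma	kegg
DB00997	doxorubicin	H00050	Synovial sarcoma	kegg
DB01181	ifosfamide	H00050	Synovial sarcoma	kegg
DB00619	imatinib	H00050	Synovial sarcoma	kegg
DB01268	sunitinib	H00050	Synovial sarcoma	kegg
DB00997	doxorubicin	H01666	Angiosarcoma	kegg
DB01181	ifosfamide	H01666	Angiosarcoma	kegg
DB01229	paclitaxel	H01666	Angiosarcoma	kegg
DB00987	cytarabine	H00001	B-cell acute lymphocytic leukemia	kegg
DB00694	daunorubicin	H00001	B-cell acute lymphocytic leukemia	kegg
DB00997	doxorubicin	H00001	B-cell acute lymphocytic leukemia	kegg
DB00563	methotrexate	H00001	B-cell acute lymphocytic leukemia	kegg
DB00635	prednisone	H00001	B-cell acute lymphocytic leukemia	kegg
DB00541	vincristine	H00001	B-cell acute lymphocytic leukemia	kegg
DB00987	cytarabine	H00002	T-cell acute lymphocytic leukemia	kegg
DB00694	daunorubicin	H00002	T-cell acute lymphocytic leukemia	kegg
DB00997	doxorubicin	H00002	T-cell acute lymphocytic leukemia	kegg
DB00563	methotrexate	H00002	T-cell acute lymphocytic leukemia	kegg
DB00635	prednisone	H00002	T-cell acute lymphocytic leukemia	kegg
DB00541	vincristine	H00002	T-cell acute lymphocytic leukemia	kegg
DB00958	carboplatin	H00054	Nasopharyngeal cancer	kegg
DB01248	docetaxel	H00054	Nasopharyngeal cancer	kegg
DB00544	fluorouracil	H00054	Nasopharyngeal cancer	kegg
DB01229	paclitaxel	H00054	Nasopharyngeal cancer	kegg
DB00317	gefitinib	H01508	Salivary gland cancer	kegg
DB00441	gemcitabine	H01508	Salivary gland cancer	kegg
DB00619	imatinib	H01508	Salivary gland cancer	kegg
DB01259	lapatinib	H01508	Salivary gland cancer	kegg
DB01204	mitoxantrone	H01508	Salivary gland cancer	kegg
DB01229	paclitaxel	H01508	Salivary gland cancer	kegg
DB00361	vinorelbine	H01508	Salivary gland cancer	kegg
DB00958	carboplatin	H01509	Tonsillar cancer	kegg
DB01248	docetaxel	H01509	Tonsillar cancer	kegg
DB00544	fluorouracil	H01509	Tonsillar cancer	kegg
DB01229	paclitaxel	H01509	Tonsillar cancer	kegg
DB00997	doxorubicin	H00044	Cancer of the anal canal	kegg
DB00544	fluorouracil	H00044	Cancer of the anal canal	kegg
DB00958	carboplatin	H01554	Fallopian tube cancer	kegg
DB01229	paclitaxel	H01554	Fallopian tube cancer	kegg
DB00958	carboplatin	H01665	Primary peritoneal carcinoma	kegg
DB01229	paclitaxel	H01665	Primary peritoneal carcinoma	kegg
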