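drug_name	pubmed	clinicaltrials
Carboplatin	Yes	Yes
Carmustine	Yes	No
Cytarabine	No	No
Dacarbazine	No	No
Daunorubicin	Yes	No
Docetaxel	Yes	Yes
Doxorubicin	Yes	Yes
Etoposide	Yes	Yes
Fluorouracil	Yes	Yes
Gefitinib	Yes	No
Gemcitabine	Yes	Yes
Hydroxyurea	No	No
Ifosfamide	Yes	No
Imatinib	Yes	No
Lapatinib	Yes	Yes
Methotrexate	Yes	Yes
Mitoxantrone	Yes	No
Octreotide	Yes	No
Paclitaxel	Yes	Yes
Prednisone	Yes	No
Sunitinib	No	Yes
Topotecan	No	No
Vincristine	Yes	No
Vinorelbine	Yes	Yes
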