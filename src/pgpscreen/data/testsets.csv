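inhibition,atpase,efflux
Vinblastine,Dipyridamole,Vinblastine
Terfenadine,Vinblastine,Taxol
Ritonavir,Taxol,Ritonavir
Loratadine,Ritonavir,Clarythromycin
Monensin,Clarithromycin,Indinavir
Reserpine,Monensin,Emetine
Nelfinavir,Amprenavir,Dipyridamole
Dipyridamole,Reserpine,Monensin
Ketoconazole,Trimethoprim,Reserpine
Loperamide,Prazosin,Colchicine
Vincristine,Doxorubicin,Itraconazole
Taxol,Vincristine,Verapamil
Vinorelbine,Mitoxantrone,Nicardipine
Clarithromycin,Etoposide,Yohimbine
Itraconazole,Methotrexate,Chlorpromazine
Etoposide,Puromycin,Midazolam
Daunorubicin,Vinorelbine,Nifedipine
Mitoxantrone,Triamterene,Methotrexate
Hoechst_33342,Mannitol,Testosterone
Emetine,Cimetidine,Practolol
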