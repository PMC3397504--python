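compound_id,inhibition,atpase,efflux
Amantadine,N,N,N
Chlorpheniramine,N,N,N
Doxorubicin,N,N,N
Itraconazole,N,N,N
Lidocaine,N,N,N
Mannitol,N,N,N
Methotrexate,N,N,N
Practolol,N,N,N
Propranolol,N,N,N
Pyridostigmine,N,N,N
Ranitidine,N,N,N
Sumatriptan,N,N,N
Triamterene,N,N,N
Yohimbine,N,N,N
Amprenavir,Y,Y,Y
Diltiazem,Y,Y,Y
Dipyridamole,Y,Y,Y
Loperamide,Y,Y,Y
Loratadine,Y,Y,Y
Monensin,Y,Y,Y
Nelfinavir,Y,Y,Y
Prazosin,Y,Y,Y
Quinidine,Y,Y,Y
Reserpine,Y,Y,Y
Ritonavir,Y,Y,Y
Saquinavir,Y,Y,Y
Terfenadine,Y,Y,Y
Vinblastine,Y,Y,Y
Elacridar,Y,N,N
GW420867,Y,N,N
Testosterone,Y,N,N
Chlorpromazine,Y,Y,N
Ketoconazole,Y,Y,N
Mebendazole,Y,Y,N
Midazolam,Y,Y,N
Nicardipine,Y,Y,N
Nifedipine,Y,Y,N
Nitrendipine,Y,Y,N
Verapamil,Y,Y,N
Chloroquine,N,N,Y
Cimetidine,N,N,Y
Colchicine,N,N,Y
Daunorubicin,N,N,Y
Dexamethasone,N,N,Y
Etoposide,N,N,Y
Hoechst_33342,N,N,Y
Mitoxantrone,N,N,Y
Neostigmine,N,N,Y
Puromycin,N,N,Y
Vincristine,N,N,Y
Vinorelbine,N,N,Y
Clarythromycin,N,Y,Y
Eletriptan,N,Y,Y
Emetine,N,Y,Y
Erythromycin,N,Y,Y
Indinavir,N,Y,Y
Taxol,N,Y,Y
Trimethoprim,N,Y,Y
Cyclosporin_A,Y,N,Y
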