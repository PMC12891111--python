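sample_code,species,genome,accession_no,origin,poly_vs_nipponbare,poly_vs_ir24,no_amp
Nipponbare,O. sativa,AA,cv. Nipponbare,Japan,,,
IR24,O. sativa,AA,cv. IR24,Philippines,,,
Eichi_C01,O. eichingeri,CC,IRGC 101424,Uganda,165,165,2
Eichi_C02,O. eichingeri,CC,IRGC 99567,Tanzania,164,162,3
Eichi_C03,O. eichingeri,CC,IRGC 101424,Uganda,165,165,2
Eichi_C04,O. eichingeri,CC,IRGC 105412,Sri Lanka,164,162,3
Offi_C05,O. officinalis,CC,IRGC 100896,Thailand,169,168,7
Offi_C06,O. officinalis,CC,IRGC 80777,Philippines,172,170,1
Offi_C07,O. officinalis,CC,IRGC 104671,Malaysia,172,171,1
Offi_C08,O. officinalis,CC,IRGC 105966,Indonesia,172,171,2
Rhizo_C09,O. rhizomatis,CC,IRGC 105432,Sri Lanka,166,165,4
Rhizo_C10,O. rhizomatis,CC,IRGC 103410,Sri Lanka,165,164,18
Rhizo_C11,O. rhizomatis,CC,IRGC 103421,Sri Lanka,164,162,4
Rhizo_C12,O. rhizomatis,CC,IRGC 105949,Sri Lanka,172,170,1
Minu_C13,O. minuta,BBCC,IRGC 101141,Philippines,169,167,4
Minu_C14,O. minuta,BBCC,IRGC 93257,Philippines,155,153,13
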