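chromosome	length_bp
chr01	43270923
chr02	35937250
chr03	36413819
chr04	35502694
chr05	29958434
chr06	31248787
chr07	29697621
chr08	28443022
chr09	23012720
chr10	23207287
chr11	29021106
chr12	27531856
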