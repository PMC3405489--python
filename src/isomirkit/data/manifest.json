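{
 "table1.tsv": "b8b8bf493fd0b4337a5d167585d1d47b76222cf65c42fbb62a3a2df955033769",
 "table2.tsv": "2b7ba1a32f89bffcea9004a38ddd267968bb691d0dd8dbfcbfc3ceb8b78db7fe"
}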