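# Deeply conserved plant miRNA families (curation label, editable).
family
miR156
miR159
miR160
miR162
miR164
miR166
miR167
miR168
miR169
miR171
miR172
miR319
miR390
miR393
miR394
miR395
miR396
miR397
miR398
miR399
miR408
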