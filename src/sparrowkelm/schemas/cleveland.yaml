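# Processed Cleveland heart table: 13 attributes + num in 0..4, binarized as 0 vs > 0
name: cleveland
header: false
delimiter: ","
label_column: 13
missing_markers: ["?", ""]
label_rule: greater_than_zero
positive_label_name: disease
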