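# BUPA liver disorders table: 6 attributes + selector (1/2)
name: bupa
header: false
delimiter: ","
label_column: 6
missing_markers: ["?", ""]
positive_values: ["1"]
negative_values: ["2"]
positive_label_name: selector_1
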