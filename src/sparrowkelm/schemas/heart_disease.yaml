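# Statlog heart table: 13 attributes + class (1 absence, 2 presence), whitespace-delimited
name: heart_disease
header: false
delimiter: "\\s+"
label_column: 13
missing_markers: ["?", ""]
positive_values: ["1", "1.0"]
negative_values: ["2", "2.0"]
positive_label_name: absence
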