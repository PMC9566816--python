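# Parkinson voice table: header row, 'name' identifier, 'status' label (1 = Parkinson's)
name: parkinson
header: true
delimiter: ","
label_column: status
drop_columns: [name]
missing_markers: ["?", ""]
positive_values: ["1"]
negative_values: ["0"]
positive_label_name: parkinsons
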