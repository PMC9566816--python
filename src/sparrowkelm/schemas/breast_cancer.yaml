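# Wisconsin breast cancer table: id + 9 attributes + class (2 benign, 4 malignant)
name: breast_cancer
header: false
delimiter: ","
label_column: 10
drop_columns: [col0]
missing_markers: ["?", ""]
positive_values: ["2"]
negative_values: ["4"]
positive_label_name: benign
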