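# Autistic Spectrum Disorder screening (children): header row, Class/ASD label (YES/NO)
name: autism_child
header: true
delimiter: ","
label_column: Class/ASD
missing_markers: ["?", ""]
positive_values: ["YES"]
negative_values: ["NO"]
categorical_columns: [gender, ethnicity, jundice, austim, contry_of_res, used_app_before, age_desc, relation]
positive_label_name: asd
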