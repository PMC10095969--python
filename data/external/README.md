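External benchmark data (not redistributed)

Place the published cadmium-experiment leaf-length table here as
`leaf_length_data.txt` (tab-delimited; `plant_id` column with C*/M*/S*
ids for control/mild/severe treatment, then timestamped leaf-length
columns in mm) to enable the external treatment-comparison benchmark in
`tests/test_acceptance.py`.  Without the file that one test fails with a
pointer to this note; everything else runs offline.
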