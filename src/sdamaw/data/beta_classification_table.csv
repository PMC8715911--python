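hydrophytes,invertebrates,ept,algae,single_indicator,classification
None,None,Absent,Absent,Absent,Ephemeral
None,None,Absent,Absent,Present,At least intermittent
None,None,Absent,Present,Absent,Need more information
None,None,Absent,Present,Present,At least intermittent
None,Few_1_19,Absent,Absent,Absent,Need more information
None,Few_1_19,Absent,Absent,Present,At least intermittent
None,Few_1_19,Absent,Present,Absent,Need more information
None,Few_1_19,Absent,Present,Present,At least intermittent
None,Few_1_19,Present,Absent,Absent,At least intermittent
None,Few_1_19,Present,Absent,Present,At least intermittent
None,Few_1_19,Present,Present,Absent,At least intermittent
None,Few_1_19,Present,Present,Present,At least intermittent
None,Many_20plus,Absent,Absent,Absent,Need more information
None,Many_20plus,Absent,Absent,Present,At least intermittent
None,Many_20plus,Absent,Present,Absent,Need more information
None,Many_20plus,Absent,Present,Present,At least intermittent
None,Many_20plus,Present,Absent,Absent,At least intermittent
None,Many_20plus,Present,Absent,Present,At least intermittent
None,Many_20plus,Present,Present,Absent,At least intermittent
None,Many_20plus,Present,Present,Present,At least intermittent
Few_1_2,None,Absent,Absent,Absent,Need more information
Few_1_2,None,Absent,Absent,Present,At least intermittent
Few_1_2,None,Absent,Present,Absent,At least intermittent
Few_1_2,None,Absent,Present,Present,At least intermittent
Few_1_2,Few_1_19,Absent,Absent,Absent,Intermittent
Few_1_2,Few_1_19,Absent,Absent,Present,Intermittent
Few_1_2,Few_1_19,Absent,Present,Absent,At least intermittent
Few_1_2,Few_1_19,Absent,Present,Present,At least intermittent
Few_1_2,Few_1_19,Present,Absent,Absent,At least intermittent
Few_1_2,Few_1_19,Present,Absent,Present,At least intermittent
Few_1_2,Few_1_19,Present,Present,Absent,At least intermittent
Few_1_2,Few_1_19,Present,Present,Present,At least intermittent
Few_1_2,Many_20plus,Absent,Absent,Absent,Intermittent
Few_1_2,Many_20plus,Absent,Absent,Present,Intermittent
Few_1_2,Many_20plus,Absent,Present,Absent,At least intermittent
Few_1_2,Many_20plus,Absent,Present,Present,At least intermittent
Few_1_2,Many_20plus,Present,Absent,Absent,At least intermittent
Few_1_2,Many_20plus,Present,Absent,Present,At least intermittent
Few_1_2,Many_20plus,Present,Present,Absent,Intermittent
Few_1_2,Many_20plus,Present,Present,Present,Intermittent
Many_3plus,None,Absent,Absent,Absent,Need more information
Many_3plus,None,Absent,Absent,Present,At least intermittent
Many_3plus,None,Absent,Present,Absent,At least intermittent
Many_3plus,None,Absent,Present,Present,At least intermittent
Many_3plus,Few_1_19,Absent,Absent,Absent,At least intermittent
Many_3plus,Few_1_19,Absent,Absent,Present,At least intermittent
Many_3plus,Few_1_19,Absent,Present,Absent,At least intermittent
Many_3plus,Few_1_19,Absent,Present,Present,At least intermittent
Many_3plus,Few_1_19,Present,Absent,Absent,Perennial
Many_3plus,Few_1_19,Present,Absent,Present,Perennial
Many_3plus,Few_1_19,Present,Present,Absent,Perennial
Many_3plus,Few_1_19,Present,Present,Present,Perennial
Many_3plus,Many_20plus,Absent,Absent,Absent,At least intermittent
Many_3plus,Many_20plus,Absent,Absent,Present,At least intermittent
Many_3plus,Many_20plus,Absent,Present,Absent,At least intermittent
Many_3plus,Many_20plus,Absent,Present,Present,At least intermittent
Many_3plus,Many_20plus,Present,Absent,Absent,Perennial
Many_3plus,Many_20plus,Present,Absent,Present,Perennial
Many_3plus,Many_20plus,Present,Present,Absent,Perennial
Many_3plus,Many_20plus,Present,Present,Present,Perennial
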