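# Per-patient surviving-variant counts of the somatic filter cascade on a
# five-patient matched whole-exome discovery cohort.
Filter	APL_1	APL_2	APL_3	APL_4	APL_5
Variants detected	55320	69713	64395	58459	61611
Somatic	4809	5824	5956	5015	6288
Absent in CR	3814	5026	4954	4340	5160
High quality	29	19	18	9	21
Coding (SNVs+indels)	20	11	12	8	13
Deleterious (SNVs+indels)	14	7	10	8	11
Unknown in dbSNP	14	5	8	7	10
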