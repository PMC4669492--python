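sample_id	accession_number	species	raw_reads	high_quality_reads	rrna_reads	final_cleaned_reads	final_cleaned_nucleotides
Sp40	PI 608712	S. tetrandra	11220670	10823210	130619	10692591	1037741475
Sp42	PI 647860	S. tetrandra	9301545	9035669	128237	8907432	859510808
Sp43	PI 647861	S. tetrandra	11968303	11705229	255255	11449974	1117491750
Sp49	PI 647864	S. turkestanica	9580222	9126379	54604	9071775	872975381
Sp50	PI 647865	S. turkestanica	15485184	15125268	331496	14793772	1438908213
Sp51	PI 662295	S. turkestanica	16640543	16276742	401807	15874935	1547778458
Sp78	S13-32	S. oleracea	11174738	10645123	93995	10551128	1025072557
Sp82	JQSZ13-3	S. oleracea	10560339	10039569	154651	9884918	959870221
Sp90	JQ13-1	S. oleracea	8445922	8255054	198762	8056292	789521055
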