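# Genome-wide curation tallies for the four cnidarian CYPomes (complete /
# partial / fragment gene counts per species) as reported by the published
# annotation. Used as in-repo worked-example input for the composition report.
species	complete	partial	fragment
Hvul	19	5	11
Adig	14	10	34
Aaur	22	15	31
Nvec	44	25	14
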