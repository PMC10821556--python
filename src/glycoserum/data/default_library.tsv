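key	class	antennae	bisected	galactoses	note
H5N2	oligomannose	0	0	0	oligomannose Man5
H6N2	oligomannose	0	0	0	oligomannose Man6
H7N2	oligomannose	0	0	0	oligomannose Man7
H8N2	oligomannose	0	0	0	oligomannose Man8
H9N2	oligomannose	0	0	0	oligomannose Man9
H4N2	other	0	0	0	paucimannose
H5N3	hybrid	1	0	0	hybrid
H5N3F1	hybrid	1	0	0	hybrid, core-fucosylated
H6N3	hybrid	1	0	0	hybrid
H5N3S1	hybrid	1	0	0	hybrid, mono-sialylated
H6N3S1	hybrid	1	0	0	hybrid, mono-sialylated
H3N3	complex	1	0	0	agalactosylated
H3N3F1	complex	1	0	0	agalactosylated, core-fucosylated
H3N4	complex	2	0	0	agalactosylated
H3N4F1	complex	2	0	0	agalactosylated, core-fucosylated
H3N5	complex	2	1	0	agalactosylated, bisected
H3N5F1	complex	2	1	0	agalactosylated, bisected, core-fucosylated
H4N3	complex	1	0	1	mono-galactosylated
H4N4	complex	2	0	1	mono-galactosylated
H4N4F1	complex	2	0	1	mono-galactosylated, core-fucosylated
H4N5	complex	2	1	1	mono-galactosylated, bisected
H4N5F1	complex	2	1	1	mono-galactosylated, bisected, core-fucosylated
H5N4	complex	2	0	2	di-galactosylated
H5N4F1	complex	2	0	2	di-galactosylated, core-fucosylated
H5N5	complex	2	1	2	di-galactosylated, bisected
H5N5F1	complex	2	1	2	di-galactosylated, bisected, core-fucosylated
H4N3S1	complex	1	0	1	mono-sialylated
H4N4S1	complex	2	0	1	mono-sialylated
H4N4S1F1	complex	2	0	1	mono-sialylated, core-fucosylated
H5N4S1	complex	2	0	2	mono-sialylated
H5N4S1F1	complex	2	0	2	mono-sialylated, core-fucosylated
H4N5S1	complex	2	1	1	mono-sialylated, bisected
H5N5S1	complex	2	1	2	mono-sialylated, bisected
H5N5S1F1	complex	2	1	2	mono-sialylated, bisected, core-fucosylated
H5N4S2	complex	2	0	2	di-sialylated biantennary
H5N4S2F1	complex	2	0	2	di-sialylated, core-fucosylated
H5N5S2	complex	2	1	2	di-sialylated, bisected
H5N5S2F1	complex	2	1	2	di-sialylated, bisected, core-fucosylated
H6N5S2	complex	3	0	3	di-sialylated triantennary
H6N5S2F1	complex	3	0	3	di-sialylated triantennary, core-fucosylated
H6N5S3	complex	3	0	3	tri-sialylated triantennary
H6N5S3F1	complex	3	0	3	tri-sialylated triantennary, core-fucosylated
H7N6S3	complex	4	0	4	tri-sialylated tetraantennary
H7N6S3F1	complex	4	0	4	tri-sialylated tetraantennary, core-fucosylated
H7N6S4	complex	4	0	4	tetra-sialylated tetraantennary
H7N6S4F1	complex	4	0	4	tetra-sialylated tetraantennary, core-fucosylated
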