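participant	gender	age_group	years_of_treatment	familial	cognitive	onset_delay	comprehension	expression	gross_motor	oral_nonverbal
1	M	C	7+	+	+	+	+	+	+	+
2	M	A	3	+		+		+	+	ND
3	F	C	6	ND		+	+	+	ND	ND
4	M	C	6			+	+	+		+
5	F	C	7+	+	+	+	+	+	+	ND
6	F	A	5			+	+	+	+	+
7	F	B	4	+		ND			+	+
8	M	B	3		+	+	ND	ND	+	+
9	F	A	4			+	+		+	+
10	M	B	5	+		+	+	+	+	+
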