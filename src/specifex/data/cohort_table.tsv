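patient_id	disease_type	onset_age	duration	gender	biopsy_age
291-1	ERD	2.3 y	2.7 y	F	9 y
375-1	ERD	2.6 y	3 y	F	2,7 y
393-1	ERD	0.9 y	0.7 y	F	13 m
393-2	ERD	0.8 y	0.8 y	F	11 m
431-1	ERD	1,5 y	3.5 y	F	3,6 y
432-2	ERD	1.5 y	2.5 y	M	3,5 y
590-2	ERD	1 y	3.5 y	F	3 y
894-1	ERD	0.6 y	10 d	M	7 m
894-2	ERD	0.4 y	10 d	F	5 m
1036-1	ERD	0.8 y	6 m	M	12 m
351-1	AD	1 y	NA	F	7 y
672-1	AD	6 m	NA	F	6,6 y
1303-1	AD	NA	NA	F	3,5 y
256-1	MLC	3 y	NA	M	15 y
773-1	MLC	3,5 y	NA	F	4,7 y
1143-1	SLS	2 m	NA	F	4 y
1179-1	SLS	At birth	NA	M	3 y
771-1	KB	3.5 m	NA	F	8 m
167-1	PMD	1 m	NA	M	4 y
767-1	PMD	At birth	NA	M	2 y
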