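protein_id	mutation	label
O75881|CYP7B1	T297A	deleterious
O75881|CYP7B1	A394D	deleterious
O75881|CYP7B1	R417C	deleterious
O75881|CYP7B1	F470I	deleterious
O75881|CYP7B1	R486C	deleterious
P08686|CYP21A2	V139E	deleterious
P08686|CYP21A2	T295N	deleterious
P08686|CYP21A2	W302R	deleterious
P08686|CYP21A2	L353R	deleterious
P08686|CYP21A2	G375S	deleterious
P08686|CYP21A2	F404S	deleterious
P08686|CYP21A2	L446P	deleterious
P08686|CYP21A2	T450P	deleterious
P08686|CYP21A2	A265V	benign
P15538|CYP11B1	M88I	deleterious
P15538|CYP11B1	W116G	deleterious
P15538|CYP11B1	P159L	deleterious
P15538|CYP11B1	A165D	deleterious
P15538|CYP11B1	R366C	deleterious
P15538|CYP11B1	R384Q	deleterious
P15538|CYP11B1	T401A	deleterious
O15528|CYP27B1	G57V	deleterious
O15528|CYP27B1	G73W	deleterious
O15528|CYP27B1	L333F	deleterious
O15528|CYP27B1	R432C	deleterious
O15528|CYP27B1	R459C	deleterious
O15528|CYP27B1	R492W	deleterious
O15528|CYP27B1	G102E	deleterious
O15528|CYP27B1	P143L	deleterious
O15528|CYP27B1	D164N	deleterious
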