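substitution	five_prime	three_prime	count
C>A	A	A	247
C>A	A	C	247
C>A	A	G	247
C>A	A	T	247
C>A	C	A	247
C>A	C	C	247
C>A	C	G	247
C>A	C	T	247
C>A	G	A	247
C>A	G	C	247
C>A	G	G	247
C>A	G	T	247
C>A	T	A	247
C>A	T	C	247
C>A	T	G	247
C>A	T	T	247
C>G	A	A	110
C>G	A	C	110
C>G	A	G	110
C>G	A	T	110
C>G	C	A	110
C>G	C	C	110
C>G	C	G	110
C>G	C	T	110
C>G	G	A	110
C>G	G	C	110
C>G	G	G	110
C>G	G	T	110
C>G	T	A	110
C>G	T	C	110
C>G	T	G	110
C>G	T	T	110
C>T	A	A	817
C>T	A	C	817
C>T	A	G	5114
C>T	A	T	817
C>T	C	A	817
C>T	C	C	817
C>T	C	G	3324
C>T	C	T	817
C>T	G	A	817
C>T	G	C	817
C>T	G	G	2301
C>T	G	T	817
C>T	T	A	817
C>T	T	C	817
C>T	T	G	2045
C>T	T	T	817
T>A	A	A	137
T>A	A	C	137
T>A	A	G	137
T>A	A	T	137
T>A	C	A	137
T>A	C	C	137
T>A	C	G	137
T>A	C	T	137
T>A	G	A	137
T>A	G	C	137
T>A	G	G	137
T>A	G	T	137
T>A	T	A	137
T>A	T	C	137
T>A	T	G	137
T>A	T	T	137
T>C	A	A	656
T>C	A	C	656
T>C	A	G	656
T>C	A	T	656
T>C	C	A	656
T>C	C	C	656
T>C	C	G	656
T>C	C	T	656
T>C	G	A	656
T>C	G	C	656
T>C	G	G	656
T>C	G	T	656
T>C	T	A	656
T>C	T	C	656
T>C	T	G	656
T>C	T	T	656
T>G	A	A	184
T>G	A	C	184
T>G	A	G	184
T>G	A	T	184
T>G	C	A	184
T>G	C	C	184
T>G	C	G	184
T>G	C	T	184
T>G	G	A	184
T>G	G	C	184
T>G	G	G	184
T>G	G	T	184
T>G	T	A	184
T>G	T	C	184
T>G	T	G	184
T>G	T	T	184
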