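variant	pasta	organisms
V17D	-3.46	S. crofa
F23R	-3.88	C. auratus
L27H	-4.10	L. chalumnae
F23G	-3.88	P. cristatus
V32G	-4.21	P. cristatus
V17G	-3.46	A. nancymaae, B. regulorum, S. boliviensis
I26A	-3.88	C. cristata, C. porcellus, F. damarensis
A25D	-3.95	C. cristata
F23A	-3.88	G. fortis, Z. albicollis
V17T	-3.46	C. harengus, E. lucius, S. araneus
L27S	-6.19	B. bison, B. mutus, C. cristata, P. cristatus
V17A	-3.46	B. bison, B. mutus, B. taurus, B. bubalis
A8E	-4.94	B. bison, B. mutus, B. taurus
Y37H	-4.94	C. hircus, O. aries
T36S	-4.94	O. princeps, O. cuniculus
K1I	-4.94	P. hamadryas
S29L	-6.36	P. alecto lq
S28L	-6.36	C. porcellus, F. damarensis, H. glaber
T30V	-6.86	O. princeps
S28V	-7.61	A. limnaeus, C. variegatus, F. heteroclitus
A25I	-7.41	P. cristatus
A5I	-4.94	O. princeps
T9I	-4.94	C. cristata, F. damarensis, H. glaber
T6I	-4.94	A. nancymaae
S19F	-6.50	C. cristata
R11W	-5.84	P. alecto lq
T4I	-4.94	A. nancymaae
N35Y	-4.94	L. chalumnae, P. gutturalis
N31V	-6.97	P. cristatus
N22I	-3.46	P. cristatus
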