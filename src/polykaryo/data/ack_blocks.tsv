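block	chromosome
A	ACK1
B	ACK1
C	ACK1
D	ACK2
E	ACK2
F	ACK3
G	ACK3
H	ACK3
I	ACK4
J	ACK4
K	ACK5
M	ACK5
O	ACK6
P	ACK6
Q	ACK6
R	ACK6
S	ACK7
T	ACK7
U	ACK7
V	ACK8
W	ACK8
X	ACK8
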